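"""Recomputable checks against the reference study's printed numbers.

The original experiment's raw mass-spectrometry data are unavailable, but
several of its headline statistics are pure arithmetic on counts it
prints: the copulatory-plug proteins' share of spectra, the mean spectra
per gene, the hypergeometric enrichment probabilities, the Fisher's exact
test on ortholog recovery, and the chi-square tails of the reported
likelihood-ratio statistics. ``verify_targets`` recomputes each with the
owning module's operation and checks it against the printed value or
significance bound.
"""

from __future__ import annotations

import pandas as pd

from .enrich import hypergeometric_tail
from .evolve import fisher_exact_2x2, lrt_pvalue

__all__ = ["REFERENCE", "verify_targets"]

#: printed summary numbers from the reference 15N-labeling study
REFERENCE = {
    "total_spectra": 27565,
    "n_identified_genes": 69,
    "plug_spectra": 10239,  # spectra on the 7 copulatory-plug proteins
    "plug_share_printed": 0.37,
    "mean_spectra_printed": 399,
    # GO population: annotated genes in the genome / in the study set
    "population_annotated": 14720,
    "study_annotated": 68,
    "antioxidant": {"K": 57, "k": 5, "bound": 0.01},
    "endopeptidase_inhibitor": {"K": 148, "k": 6, "bound": 0.02},
    # one-to-one ortholog recovery: 29/54 study vs 303/429 non-study genes
    "ortholog_table": (29, 25, 303, 126),
    "ortholog_bound": 0.02,
    # (2ΔL, df, printed bound) for the reported site-model LRTs
    "lrt_statistics": [
        ("lactotransferrin_m7_vs_m8", 29.8, 2, 1e-6),
        ("lactotransferrin_m8a_vs_m8", 22.9, 1, 1e-5),
        ("timp1_m7_vs_m8", 9.81, 2, 0.01),
        ("timp1_m8a_vs_m8", 4.82, 1, 0.03),
    ],
}


def _chi2_tail(two_delta_l: float, df: int) -> float:
    # lrt_pvalue takes log-likelihoods; feed it the gap directly
    _, p = lrt_pvalue(0.0, two_delta_l / 2.0, df)
    return p


def verify_targets() -> pd.DataFrame:
    """Recompute every printed-number check; returns a pass/fail table."""
    rows = []

    share = REFERENCE["plug_spectra"] / REFERENCE["total_spectra"]
    rows.append(
        {
            "target": "plug_spectral_share",
            "value": share,
            "reference": REFERENCE["plug_share_printed"],
            "rule": "rounds to printed share",
            "passed": round(share, 2) == REFERENCE["plug_share_printed"],
        }
    )

    mean_spectra = REFERENCE["total_spectra"] / REFERENCE["n_identified_genes"]
    rows.append(
        {
            "target": "mean_spectra_per_gene",
            "value": mean_spectra,
            "reference": REFERENCE["mean_spectra_printed"],
            "rule": "rounds to printed mean",
            "passed": round(mean_spectra) == REFERENCE["mean_spectra_printed"],
        }
    )

    for name in ("antioxidant", "endopeptidase_inhibitor"):
        spec = REFERENCE[name]
        p = hypergeometric_tail(
            REFERENCE["population_annotated"],
            spec["K"],
            REFERENCE["study_annotated"],
            spec["k"],
        )
        rows.append(
            {
                "target": f"{name}_enrichment_p",
                "value": p,
                "reference": spec["bound"],
                "rule": "below printed bound",
                "passed": p < spec["bound"],
            }
        )

    p_fisher = fisher_exact_2x2(*REFERENCE["ortholog_table"])
    rows.append(
        {
            "target": "ortholog_recovery_fisher_p",
            "value": p_fisher,
            "reference": REFERENCE["ortholog_bound"],
            "rule": "below printed bound",
            "passed": p_fisher < REFERENCE["ortholog_bound"],
        }
    )

    for name, two_dl, df, bound in REFERENCE["lrt_statistics"]:
        p = _chi2_tail(two_dl, df)
        rows.append(
            {
                "target": f"{name}_p",
                "value": p,
                "reference": bound,
                "rule": "below printed bound",
                "passed": p < bound,
            }
        )

    return pd.DataFrame(
        rows, columns=["target", "value", "reference", "rule", "passed"]
    )
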