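"""Multicopper-oxidase activity quantification and relative-activity stats.

The 2,6-DMP assay follows oxidized 2,6-dimethoxyphenol at 468 nm;
Beer-Lambert with epsilon = 14,800 M^-1 cm^-1 converts the absorbance rate
into a molar rate, expressed as specific activity in nmol of substrate
oxidized per minute per mg protein.  Strain comparisons are expressed as
percent of the wild-type mean with the Satterthwaite-corrected (Welch)
two-sided t-test; p-values are annotated with the conventional star
labels, no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

EPSILON_DMP = 14800.0  # M^-1 cm^-1, oxidized 2,6-DMP


@dataclass(frozen=True)
class AssayConfig:
    """Spectrophotometric assay geometry and protein load."""

    epsilon: float = EPSILON_DMP
    path_cm: float = 1.0
    volume_L: float = 1e-3
    protein_mg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_cm", "volume_L", "protein_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def specific_activity(deltaA_per_min: float, cfg: AssayConfig) -> float:
    """Specific activity in nmol min^-1 mg^-1 from an absorbance rate.

    Beer-Lambert: concentration rate = dA / (epsilon * path); times the
    reaction volume gives mol/min, scaled to nmol and per mg protein.
    """
    if deltaA_per_min < 0:
        raise ValueError("deltaA_per_min must be >= 0")
    molar_per_min = deltaA_per_min / (cfg.epsilon * cfg.path_cm)
    return molar_per_min * cfg.volume_L * 1e9 / cfg.protein_mg


def relative_activity(sample_values, wt_values) -> tuple[float, float]:
    """Percent of wild-type mean, with the sample sd on the same scale."""
    sample = np.asarray(sample_values, dtype=float)
    wt = np.asarray(wt_values, dtype=float)
    wt_mean = wt.mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean is zero; relative activity undefined")
    pct = 100.0 * sample.mean() / wt_mean
    sd = 100.0 * sample.std(ddof=1) / wt_mean if sample.size > 1 else 0.0
    return float(pct), float(sd)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t-test (Satterthwaite degrees of freedom).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b); df by the
    Satterthwaite formula.  Zero variance in both samples with equal means
    returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def significance_stars(p: float) -> str:
    """Conventional significance labels: * <=0.05, ** <=0.01, *** <=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def activity_report(strain_values: dict[str, list[float]], wt_strain: str
                    ) -> list[dict]:
    """Per-strain relative activity, Welch p versus wild type, and stars."""
    if wt_strain not in strain_values:
        raise KeyError(f"wild-type strain {wt_strain!r} missing from table")
    wt = strain_values[wt_strain]
    rows = []
    for strain in sorted(strain_values):
        pct, sd = relative_activity(strain_values[strain], wt)
        if strain == wt_strain:
            t, df, p = 0.0, float(2 * (len(wt) - 1)), 1.0
        else:
            t, df, p = welch_t_test(strain_values[strain], wt)
        rows.append(
            {
                "strain": strain,
                "pct_of_wt": pct,
                "sd": sd,
                "t": t,
                "df": df,
                "p": p,
                "stars": significance_stars(p) if strain != wt_strain else "",
            }
        )
    return rows
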