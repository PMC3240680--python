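"""Optical-sensitivity ratios and pupil-geometry descriptors.

The optical ratio OPT = A²/(RD·PND) — squared aperture over the product of
retina diameter and posterior nodal distance — indexes the light-gathering
capacity of a camera-type eye. True optical quantities are not measurable
on preserved material, so three morphological proxies are computed from the
untransformed species trait means:

* ``opt_morph1`` = LD² / (ED·AL) — lens diameter as the aperture proxy,
* ``opt_morph2`` = PDmin² / (ED·AL) — smallest pupil diameter instead,
* ``opt_morph3`` = (LD·PDmin) / (ED·PDmax) — aperture and pupil-shape
  information combined, cancelling the focal-length-linked LD/AL ratio.

Two pupil descriptors accompany them: pupil roundness PDmin/PDmax (1 for a
circular pupil) and the aphakic-gap fraction 1 − LD/PDmax, the "lensless"
share of the long pupil axis (may be negative when the lens is wider than
the pupil's long axis; preserved, not clipped).

All ratios are scale-invariant: multiplying every trait of a species by a
common factor leaves the profile unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RATIO_COLUMNS",
    "GapComparison",
    "optical_profile",
    "aphakic_gap_compare",
    "ratio_variances",
]

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ("opt_morph1", "opt_morph2", "opt_morph3")


def optical_profile(species: pd.DataFrame) -> pd.DataFrame:
    """Per-species optical ratios and pupil descriptors.

    Expects a natural-scale species table (``species_means`` output) and
    returns one row per species with ``species_id, diel_class, opt_morph1,
    opt_morph2, opt_morph3, pupil_roundness, aphakic_gap_frac``.
    """
    for t in ("ed", "al", "ld", "pdmax", "pdmin"):
        if (species[t] <= 0).any():
            bad = species.loc[species[t] <= 0, "species_id"].tolist()
            raise ValueError(f"non-positive {t} for species {bad}")
    ed = species["ed"].to_numpy(dtype=float)
    al = species["al"].to_numpy(dtype=float)
    ld = species["ld"].to_numpy(dtype=float)
    pdmax = species["pdmax"].to_numpy(dtype=float)
    pdmin = species["pdmin"].to_numpy(dtype=float)

    out = species[["species_id", "diel_class"]].copy()
    out["opt_morph1"] = ld**2 / (ed * al)
    out["opt_morph2"] = pdmin**2 / (ed * al)
    out["opt_morph3"] = (ld * pdmin) / (ed * pdmax)
    out["pupil_roundness"] = pdmin / pdmax
    out["aphakic_gap_frac"] = 1.0 - ld / pdmax
    n_neg = int((out["aphakic_gap_frac"] < 0).sum())
    if n_neg:
        logger.info("aphakic_gap_frac negative for %d species "
                    "(lens wider than long pupil axis)", n_neg)
    return out


@dataclass
class GapComparison:
    """Class means of the aphakic gap (% of PDmax) and a two-sample t-test."""

    mean_pct: dict[str, float]
    t_statistic: float
    df: float
    p_value: float


def aphakic_gap_compare(profiles: pd.DataFrame,
                        by: str = "diel_class") -> GapComparison:
    """Compare the aphakic-gap fraction between diel classes.

    Means are reported as percent of the largest pupil diameter; the test
    is Welch's two-sample t-test on the per-species fractions.
    """
    classes = list(pd.unique(profiles[by]))
    if len(classes) < 2:
        raise ValueError("need at least two classes for a gap comparison")
    samples = {
        c: profiles.loc[profiles[by] == c, "aphakic_gap_frac"].to_numpy()
        for c in classes
    }
    for c, s in samples.items():
        if s.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 species")
    a, b = (samples[c] for c in classes[:2])
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite df
    va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    means = {c: 100.0 * float(np.mean(s)) for c, s in samples.items()}
    return GapComparison(mean_pct=means, t_statistic=float(t), df=float(df),
                         p_value=float(p))


def ratio_variances(profiles: pd.DataFrame,
                    by: str = "diel_class",
                    log_scale: bool = False) -> pd.DataFrame:
    """Sample variance of each optical ratio, per diel class.

    Variances are taken on the natural ratio values by default; set
    ``log_scale=True`` for variances of log10 ratios instead.
    """
    classes = list(pd.unique(profiles[by]))
    for c in classes:
        if (profiles[by] == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 species")
    rows = []
    for c in classes:
        sub = profiles[profiles[by] == c]
        row: dict[str, object] = {by: c, "n": int(len(sub))}
        for col in RATIO_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            if log_scale:
                vals = np.log10(vals)
            row[col] = float(np.var(vals, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
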