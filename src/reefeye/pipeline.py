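"""One-call reproduction of the full analysis on a specimen table.

Stage order: preprocess (eye averages → species means → log table) →
SMA regressions (eye size vs body mass with anguilliform exclusion, the
three optical-ratio framings, pupil shape, lens-vs-pupil isometry) →
optical ratios (profiles, aphakic-gap t-test, per-class ratio variances)
→ PCA (3- and 5-trait, size-axis diagnostics, MANOVA on PCs 2–3, convex
hulls) → discriminant analysis (all four methods on both trait sets, RDA
lambda scan) → rarefaction. Every reported number is produced by one of
the library operations; this layer only sequences and serialises them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core_data, discriminant, morphospace, optics, rarefaction, sma
from .core_data import log_transform, species_means
from .morphospace import FIVE_TRAIT_SET, THREE_TRAIT_SET

__all__ = ["run_all", "analysis_summary"]

TRAIT_SETS = {"three": list(THREE_TRAIT_SET), "five": list(FIVE_TRAIT_SET)}


def _fit_to_dict(fit: sma.SMAFit) -> dict:
    return dataclasses.asdict(fit)


def analysis_summary(records: Sequence[core_data.SpecimenRecord],
                     n_rarefaction: int = 1000,
                     seed: int | None = None,
                     rda_gamma: float = 0.0) -> dict:
    """Run every analysis stage and return one nested summary dict.

    ``n_rarefaction`` controls the resampling iteration count (the full
    analysis uses 100,000; smaller values trade precision of the
    rarefaction p for speed).
    """
    species = species_means(records)
    logs = log_transform(species)

    summary: dict = {
        "n_specimens": len(records),
        "n_species": int(len(species)),
        "n_by_class": species["diel_class"].value_counts().to_dict(),
        "seed": seed,
        "n_rarefaction": n_rarefaction,
    }

    # --- SMA stage ---------------------------------------------------------
    eye_size = sma.fit_group_lines(species, preset="eye_size",
                                   exclude_anguilliform=True, b0=1.0 / 3.0)
    pupil = sma.fit_group_lines(species, preset="pupil_shape")
    opt1 = sma.fit_group_lines(species, preset="opt_morph1")
    opt2 = sma.fit_group_lines(species, preset="opt_morph2")
    opt3 = sma.fit_group_lines(species, preset="opt_morph3")
    lens_pupil = sma.fit_group_lines(species, preset="lens_vs_pupil", b0=1.0)

    def _lines(res: sma.GroupLinesResult) -> dict:
        out = {
            "pooled": _fit_to_dict(res.pooled),
            "groups": {lab: _fit_to_dict(f) for lab, f in res.common.fits.items()},
            "slope_equality_p": res.common.slope_equality_p,
            "b_common": res.common.b_common,
            "intercepts_at_common_slope": res.common.intercepts,
            "intercept_p": res.common.intercept_p,
        }
        if res.pooled_slope_test is not None:
            out["pooled_b0_test_p"] = res.pooled_slope_test.p_value
            out["group_b0_test_p"] = {
                lab: t.p_value for lab, t in res.group_slope_tests.items()
            }
        return out

    summary["sma"] = {
        "eye_size_vs_mass": _lines(eye_size),
        "pupil_shape": _lines(pupil),
        "opt_morph1": _lines(opt1),
        "opt_morph2": _lines(opt2),
        "opt_morph3": _lines(opt3),
        "lens_vs_pupil": _lines(lens_pupil),
    }
    summary["sma"]["eye_size_vs_mass"]["size_factor_nocturnal_over_diurnal"] = (
        eye_size.common.size_factor("nocturnal", "diurnal")
    )

    # --- optics stage ------------------------------------------------------
    profiles = optics.optical_profile(species)
    gap = optics.aphakic_gap_compare(profiles)
    variances = optics.ratio_variances(profiles)
    summary["optics"] = {
        "aphakic_gap_pct": gap.mean_pct,
        "aphakic_gap_p": gap.p_value,
        "ratio_variances": variances.set_index("diel_class")[
            list(optics.RATIO_COLUMNS)
        ].to_dict(orient="index"),
        "mean_opt_morph3": profiles.groupby("diel_class")["opt_morph3"]
        .mean().to_dict(),
    }

    # --- morphospace stage -------------------------------------------------
    summary["pca"] = {}
    for name, variables in TRAIT_SETS.items():
        pca = morphospace.pca_correlation(logs, variables)
        size_rep = morphospace.size_axis_report(pca, logs)
        labels = logs["diel_class"].to_numpy()
        man = morphospace.manova_two_groups(pca.scores[:, 1:3], labels)
        entry = {
            "pct_variance": pca.pct_variance.tolist(),
            "loadings": pca.loadings.tolist(),
            "size_axis_r2": size_rep["r_squared"].tolist(),
            "manova_p": man.p_value,
            "wilks_lambda": man.wilks_lambda,
        }
        pts = {
            cls: pca.scores[labels == cls][:, 1:3]
            for cls in ("nocturnal", "diurnal")
        }
        try:
            hulls = morphospace.hull_occupancy(pts)
            entry["hull_areas"] = hulls.areas
            entry["n_nocturnal_outside_diurnal_hull"] = int(
                hulls.outside["nocturnal"].sum()
            )
        except ValueError:
            entry["hull_areas"] = None
        summary["pca"][name] = entry

    # --- discriminant stage ------------------------------------------------
    summary["discriminant"] = {}
    all_results = []
    for name, variables in TRAIT_SETS.items():
        entry = {}
        for method in ("lda", "qda", "fda"):
            res = discriminant.da_fit_predict(logs, variables, method=method)
            entry[method] = {
                "misclassified_fraction": res.misclassified_fraction,
                "misclassified": res.misclassified,
            }
            all_results.append(res)
        scan = discriminant.rda_lambda_scan(logs, variables, gamma=rda_gamma)
        entry["rda_scan"] = {
            "best_fraction": scan.best_fraction,
            "best_lambdas": scan.best_lambdas,
        }
        best_rda = discriminant.da_fit_predict(
            logs, variables, method="rda",
            lambda_=scan.best_lambdas[0], gamma=rda_gamma,
        )
        all_results.append(best_rda)
        summary["discriminant"][name] = entry
    summary["discriminant"]["consistently_misclassified"] = (
        discriminant.consistently_misclassified(all_results)
    )

    # --- rarefaction stage -------------------------------------------------
    rar = rarefaction.rarefy_diversity(
        logs, variables=FIVE_TRAIT_SET, n_iter=n_rarefaction, seed=seed
    )
    summary["rarefaction"] = rar.summary()
    return summary


def run_all(records: Sequence[core_data.SpecimenRecord],
            out_dir: str | Path,
            n_rarefaction: int = 1000,
            seed: int | None = None) -> dict:
    """Run the full analysis and write CSV/JSON outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species = species_means(records)
    logs = log_transform(species)
    species.to_csv(out / "species_means.csv", index=False)
    logs.to_csv(out / "log_traits.csv", index=False)
    optics.optical_profile(species).to_csv(out / "optical_profiles.csv",
                                           index=False)
    summary = analysis_summary(records, n_rarefaction=n_rarefaction,
                               seed=seed)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
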