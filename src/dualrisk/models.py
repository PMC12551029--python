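"""The two analysis stages over the score panel.

Stage 1 (prediction of change): a progressive series of FIML regressions
of wave-6 cardiac risk on baseline covariates (Model 1: age, sex, CRI5),
plus the wave-5 alcohol and inflammation scores (Model 2), plus wave-5
self-reported binge drinking (Model 3), plus an EIS5 x age interaction
with mean-centered parents (Model 4).  Standardized coefficients and the
ΔR² chain are reported per step, with couple-cluster-robust SEs.

Stage 2 (correlated change): with exactly two waves, a person-specific
random slope is not identified separately from residual variation, so
the primary formulation treats each person's change as the simple
difference between waves (one wave unit ≈ 3 years): CRI change is
regressed on age-40, sex, baseline CRI and the ATS/EIS differences, raw
coefficients reported.  A stacked person-wave formulation with
within-person-centered predictors is available as a labelled sensitivity
analysis.

All models derive from the joint-normal FIML fit, so rows with a missing
outcome or missing predictors still contribute; clusters are couples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mvn import (
    EstimationError,
    FIMLRegression,
    FIMLRegressionResults,
    delta_r2,
    em_mvn,
)
from .simulate import to_person_wide

PREDICTION_MODELS = {
    "Model 1": ["age", "sex", "cri5"],
    "Model 2": ["age", "sex", "cri5", "ats5", "eis5"],
    "Model 3": ["age", "sex", "cri5", "ats5", "eis5", "binge"],
    "Model 4": ["age", "sex", "cri5", "ats5", "eis5", "binge", "eis5_x_age"],
}

CHANGE_MODELS = {
    "Model 1": ["age40", "sex", "cri5"],
    "Model 2": ["age40", "sex", "cri5", "d_ats", "d_eis"],
}


@dataclass
class ModelSpec:
    """One named regression in a series."""

    name: str
    outcome: str
    predictors: list
    cluster: str = "couple_id"
    interactions: list = field(default_factory=list)  # (a, b) pairs, mean-centered
    centering: dict = field(default_factory=dict)     # column -> constant

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.predictors or b not in self.predictors:
                raise ValueError(
                    f"interaction parents ({a}, {b}) must appear as main effects"
                )
        for c, v in self.centering.items():
            if not np.isfinite(v):
                raise ValueError(f"centering constant for {c!r} must be finite")


def _star(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class SeriesReport:
    """Ordered fits of a nested model series with the ΔR² chain."""

    name: str
    model_names: list
    fits: list  # FIMLRegressionResults, same order
    coefficient_scale: str = "standardized"  # which column render() stars

    @property
    def delta_r2_chain(self) -> list:
        out = [np.nan]
        for prev, cur in zip(self.fits, self.fits[1:]):
            out.append(delta_r2(cur, prev))
        return out

    def fit(self, model_name: str) -> FIMLRegressionResults:
        return self.fits[self.model_names.index(model_name)]

    def render(self) -> str:
        """Text table: one row per predictor, one column per model."""
        rows: list[str] = []
        seen: list[str] = []
        for f in self.fits:
            for t in f.model.predictors:
                if t not in seen:
                    seen.append(t)
        width = 14
        header = f"{'Predictor':<16}" + "".join(f"{m:>{width}}" for m in self.model_names)
        rows.append(self.name)
        rows.append(header)
        for term in seen:
            cells = []
            for f in self.fits:
                if term in f.model.predictors:
                    if self.coefficient_scale == "standardized":
                        val = f.params_standardized[term]
                    else:
                        val = f.params[term]
                    cells.append(f"{val:.4f}{_star(f.pvalues[term]):<2}".rjust(width))
                else:
                    cells.append(" " * width)
            rows.append(f"{term:<16}" + "".join(cells))
        rows.append(
            f"{'R^2':<16}" + "".join(f"{f.rsquared:>{width}.3f}" for f in self.fits)
        )
        dr2 = self.delta_r2_chain
        rows.append(
            f"{'dR^2':<16}"
            + "".join(
                (" " * width) if np.isnan(v) else f"{v:>{width}.3f}" for v in dr2
            )
        )
        rows.append("Note: * p < 0.05, ** p < 0.01 (two-tailed tests).")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "models": {
                m: {
                    **f.to_dict(),
                    "fit_indices": f.fit_indices().to_dict(),
                }
                for m, f in zip(self.model_names, self.fits)
            },
            "delta_r2": [None if np.isnan(v) else v for v in self.delta_r2_chain],
        }


def _require(table: pd.DataFrame, cols) -> None:
    missing = [
        c for c in cols if c not in table.columns or table[c].notna().sum() == 0
    ]
    if missing:
        raise EstimationError(f"required columns missing or empty: {missing}")


def _as_wide(table: pd.DataFrame, sheet: pd.DataFrame | None) -> pd.DataFrame:
    if "wave" in table.columns:  # long panel: pivot to one row per person
        return to_person_wide(table, sheet)
    return table.copy()


def run_prediction_series(
    table: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    cluster: str = "couple_id",
    **fit_kwargs,
) -> SeriesReport:
    """Fit the four-step prediction-of-change series (outcome: CRI at wave 6).

    ``table`` is either a long score panel (with ``wave``; a sample
    sheet may supply demographics) or an already person-wide table with
    columns age, sex, binge, ats5, eis5, cri5, cri6 and the cluster id.
    """
    wide = _as_wide(table, sheet)
    _require(wide, ["age", "sex", "cri5", "ats5", "eis5", "cri6", cluster])
    wide = wide.copy()
    # interaction parents mean-centered before the product; main effects
    # stay on their raw scales
    eis_c = wide["eis5"] - wide["eis5"].mean()
    age_c = wide["age"] - wide["age"].mean()
    wide["eis5_x_age"] = eis_c * age_c

    fits = []
    for name, preds in PREDICTION_MODELS.items():
        if "binge" in preds and wide["binge"].notna().sum() < 2:
            raise EstimationError("binge column required for Models 3-4 is empty")
        fits.append(FIMLRegression(wide, "cri6", preds, cluster=cluster).fit(**fit_kwargs))
    return SeriesReport(
        name="Prediction of wave-6 cardiac risk (standardized coefficients)",
        model_names=list(PREDICTION_MODELS),
        fits=fits,
        coefficient_scale="standardized",
    )


def run_change_models(
    table: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    formulation: str = "difference",
    cluster: str = "couple_id",
    **fit_kwargs,
) -> SeriesReport:
    """Fit the correlated-change models (outcome: change in cardiac risk).

    ``formulation="difference"`` (primary): person slopes are simple
    between-wave differences; both-wave completers identify the slope
    terms and partially observed people contribute through FIML over the
    joint vector.  ``formulation="stacked"`` (sensitivity): person-wave
    rows with within-person-centered ATS/EIS (the within coefficients
    are the change effects) plus the person means as between terms.
    Raw coefficients are reported.
    """
    if formulation not in ("difference", "stacked"):
        raise ValueError(f"unknown formulation {formulation!r}")
    wide = _as_wide(table, sheet)
    _require(wide, ["age", "sex", "cri5", "cri6", "ats5", "ats6", "eis5", "eis6", cluster])
    wide = wide.copy()
    wide["age40"] = wide["age"] - 40.0

    if formulation == "difference":
        wide["d_cri"] = wide["cri6"] - wide["cri5"]
        wide["d_ats"] = wide["ats6"] - wide["ats5"]
        wide["d_eis"] = wide["eis6"] - wide["eis5"]
        if wide["d_cri"].notna().sum() == 0:
            raise EstimationError(
                "difference formulation needs at least one both-wave completer"
            )
        fits = [
            FIMLRegression(wide, "d_cri", preds, cluster=cluster).fit(**fit_kwargs)
            for preds in CHANGE_MODELS.values()
        ]
        return SeriesReport(
            name="Covariation of change (difference formulation, raw coefficients)",
            model_names=list(CHANGE_MODELS),
            fits=fits,
            coefficient_scale="raw",
        )

    # stacked sensitivity formulation
    rows = []
    for w in (5, 6):
        rows.append(
            pd.DataFrame(
                {
                    "person_id": wide["person_id"],
                    cluster: wide[cluster],
                    "age40": wide["age40"],
                    "sex": wide["sex"],
                    "cri5": wide["cri5"],
                    "cri": wide[f"cri{w}"],
                    "ats": wide[f"ats{w}"],
                    "eis": wide[f"eis{w}"],
                }
            )
        )
    long = pd.concat(rows, ignore_index=True)
    long["wave_c"] = np.repeat([-0.5, 0.5], len(wide))  # time main effect
    pm = long.groupby("person_id")[["ats", "eis"]].transform("mean")
    long["ats_between"] = pm["ats"]
    long["eis_between"] = pm["eis"]
    long["d_ats"] = long["ats"] - pm["ats"]   # within-person change terms
    long["d_eis"] = long["eis"] - pm["eis"]
    specs = {
        "Model 1": ["age40", "sex", "cri5", "wave_c"],
        "Model 2": ["age40", "sex", "cri5", "wave_c",
                    "ats_between", "eis_between", "d_ats", "d_eis"],
    }
    fits = [
        FIMLRegression(long, "cri", preds, cluster=cluster).fit(**fit_kwargs)
        for preds in specs.values()
    ]
    return SeriesReport(
        name="Covariation of change (stacked sensitivity formulation, raw coefficients)",
        model_names=list(specs),
        fits=fits,
        coefficient_scale="raw",
    )


DESCRIPTIVE_VARS = ["age", "sex", "binge", "ats5", "eis5", "cri5", "ats6", "eis6", "cri6"]


def descriptives_table(
    table: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    cutoff: float = 2.35,
) -> dict:
    """FIML descriptives over demographics and the six score variables.

    Returns FIML means/SDs and the FIML correlation matrix (EM over the
    person-wide table), the per-pair available-N matrix, and the share
    of observations above the elevated-alcohol cutoff per wave.
    """
    wide = _as_wide(table, sheet)
    _require(wide, DESCRIPTIVE_VARS)
    block = wide[DESCRIPTIVE_VARS]
    fit = em_mvn(block)
    notna = block.notna().to_numpy().astype(int)
    pair_n = pd.DataFrame(
        notna.T @ notna, index=DESCRIPTIVE_VARS, columns=DESCRIPTIVE_VARS
    )
    pct_elev = {}
    for w in (5, 6):
        a = wide[f"ats{w}"].dropna()
        if len(a):
            pct_elev[f"w{w}"] = float((a > cutoff).mean())
    return {
        "variables": DESCRIPTIVE_VARS,
        "fiml_means": pd.Series(fit.mean, index=DESCRIPTIVE_VARS),
        "fiml_sds": pd.Series(fit.sds, index=DESCRIPTIVE_VARS),
        "fiml_corr": pd.DataFrame(fit.corr, index=DESCRIPTIVE_VARS, columns=DESCRIPTIVE_VARS),
        "pair_n": pair_n,
        "pct_elevated": pct_elev,
        "n_individuals": int(len(wide)),
        "fiml_converged": bool(fit.converged),
    }
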