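"""Synthetic dyadic two-wave cohorts with configurable score structure.

The generator emulates the design of a couples study in which both
partners are followed over two waves three years apart and provide
methylation-derived risk scores (ATS, EIS, CRI) at each wave:

* person-level 6-vectors (ATS5, EIS5, CRI5, ATS6, EIS6, CRI6) drawn from
  a target correlation matrix, with a within-couple correlation
  (``couple_icc``) shared across all components;
* ages and sexes drawn independently per person;
* a three-category participation pattern (both waves / wave 5 only /
  wave 6 only) applied per person, optionally with a logistic
  dependence of wave-6 dropout on the wave-5 ATS (a testable
  missing-at-random mechanism);
* optional *structural* modes in which wave-6 cardiac risk (or its
  within-person change) is generated from an explicit coefficient block,
  so the fitting modules can be checked for parameter recovery;
* :func:`embed_betas` inverts the scoring step, producing a CpG-level
  beta matrix from which the scoring module recovers the target scores.

All randomness flows through one ``numpy`` Generator seeded from the
config, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ATS_ASSAY_COLUMNS, BetaMatrix, WeightTable, obs_key
from .scores import ATS_CUTOFF, ScoreConfig, classify_elevated, inverse_mvalue
from .mvn import em_mvn

#: Order of the six score variables throughout this module.
SCORE_VARS = ("ats5", "eis5", "cri5", "ats6", "eis6", "cri6")

# Printed two-wave correlation structure: stabilities and within-wave
# cross-trait correlations for (ATS, EIS, CRI).
STABILITIES = {"ats": 0.846, "eis": 0.639, "cri": 0.479}
WITHIN_WAVE = {
    5: {("ats", "eis"): 0.403, ("ats", "cri"): -0.378, ("eis", "cri"): -0.580},
    6: {("ats", "eis"): 0.413, ("ats", "cri"): -0.434, ("eis", "cri"): -0.650},
}

#: Table-1-style standardized prediction effects on wave-6 cardiac risk
#: (full model: baseline covariates plus both wave-5 scores).
DEFAULT_PREDICTION_EFFECTS = {
    "age": -0.108,
    "sex": 0.112,
    "cri5": 0.368,
    "ats5": -0.193,
    "eis5": -0.042,
}

#: Table-2-style raw change-model effects on the cardiac-risk difference
#: (beta-fraction units per unit of each predictor).
DEFAULT_CHANGE_EFFECTS = {
    "age40": 0.0001,
    "sex": 0.0106,
    "cri5": 0.6098,
    "d_ats": -0.0004,
    "d_eis": -0.0145,
}


class GeneratorError(ValueError):
    """The generator configuration is invalid."""


def nearest_psd_correlation(r: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are floored at ``eig_floor`` and the result rescaled to
    unit diagonal (one-step Higham-style projection, sufficient for the
    mildly indefinite matrices the product rule can produce).
    """
    r = 0.5 * (r + r.T)
    vals, vecs = np.linalg.eigh(r)
    vals = np.maximum(vals, eig_floor)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def default_target_corr() -> np.ndarray:
    """Assemble the 6x6 target correlation over (ATS5, EIS5, CRI5, ATS6, EIS6, CRI6).

    Nine entries are fixed from the printed two-wave structure
    (stabilities plus within-wave cross-trait correlations); the six
    cross-wave cross-trait entries, which are not printed, are filled by
    the product rule ``r(X5, Y6) = r(X5, Y5) * r(Y5, Y6)``, and the
    matrix is projected to the nearest PSD correlation matrix.
    """
    traits = ("ats", "eis", "cri")
    idx = {f"{t}{w}": i for i, (w, t) in enumerate([(w, t) for w in (5, 6) for t in traits])}
    r = np.eye(6)

    def put(a, b, v):
        r[idx[a], idx[b]] = v
        r[idx[b], idx[a]] = v

    for t, s in STABILITIES.items():
        put(f"{t}5", f"{t}6", s)
    for w, pairs in WITHIN_WAVE.items():
        for (a, b), v in pairs.items():
            put(f"{a}{w}", f"{b}{w}", v)
    # product rule for the six unprinted cross-wave cross-trait entries
    for x in traits:
        for y in traits:
            if x == y:
                continue
            r_within = WITHIN_WAVE[5].get((x, y), WITHIN_WAVE[5].get((y, x)))
            put(f"{x}5", f"{y}6", r_within * STABILITIES[y])
    r = nearest_psd_correlation(r)
    # reorder to SCORE_VARS = ats5, eis5, cri5, ats6, eis6, cri6 (already is)
    return r


@dataclass
class GeneratorConfig:
    """Distributional targets for the synthetic dyadic cohort.

    Attributes
    ----------
    n_couples : int
        Couples to simulate; each contributes two partners.
    target_corr : 6x6 array, optional
        Correlation over (ATS5, EIS5, CRI5, ATS6, EIS6, CRI6); defaults
        to the printed two-wave structure with product-rule fill-in.
    means, sds : dict
        Marginals per score variable.  ATS means default to 2.201 (W5)
        and 2.195 (W6) with SD 1; EIS is on its z scale (0, 1); CRI uses
        mid-range beta-fraction marginals (0.55, 0.05), chosen to avoid
        boundary clamping and documented as arbitrary.
    couple_icc : float
        Within-couple correlation of the person-level latent factors.
    age_mean, age_sd, p_female : float
        Demographics; sex is coded 1 = female, 0 = male.
    missingness : (p_both, p_w5_only, p_w6_only)
        Participation-pattern probabilities per person; default matches
        a 271/77/35 split of 383 individuals.
    mar_logistic_coef : float
        When nonzero, wave-6 dropout probability depends on the wave-5
        ATS z-score through a logistic link (MAR mechanism); 0 = MCAR.
    mode : {"correlation", "structural", "structural_change"}
        "correlation" draws all six scores from ``target_corr``;
        "structural" generates CRI6 from ``prediction_effects``
        (standardized coefficients on age, sex, CRI5, ATS5, EIS5);
        "structural_change" generates the CRI difference from
        ``change_effects`` (raw coefficients on age-40, sex, CRI5, and
        the ATS/EIS differences) plus a residual of SD
        ``change_resid_sd``.
    binge_loading : float
        Correlation of the wave-5 self-reported binge score (z scale)
        with the wave-5 ATS; binge is generated independent of CRI6
        given ATS5.
    ats_locus_noise_sd : float
        Spread of the four per-locus assay values around ATS/4 (their
        deviations sum to zero, so the fixed-reference ATS is exact).
    seed : int
        Base seed for the generator.
    """

    n_couples: int = 221
    waves: tuple = (5, 6)
    target_corr: np.ndarray | None = None
    means: dict = field(
        default_factory=lambda: {
            "ats5": 2.201, "eis5": 0.0, "cri5": 0.55,
            "ats6": 2.195, "eis6": 0.0, "cri6": 0.55,
        }
    )
    sds: dict = field(
        default_factory=lambda: {
            "ats5": 1.0, "eis5": 1.0, "cri5": 0.05,
            "ats6": 1.0, "eis6": 1.0, "cri6": 0.05,
        }
    )
    couple_icc: float = 0.2
    age_mean: float = 44.61
    age_sd: float = 8.22
    p_female: float = 0.54
    missingness: tuple = (271 / 383, 77 / 383, 35 / 383)
    mar_logistic_coef: float = 0.0
    mode: str = "correlation"
    prediction_effects: dict = field(default_factory=lambda: dict(DEFAULT_PREDICTION_EFFECTS))
    change_effects: dict = field(default_factory=lambda: dict(DEFAULT_CHANGE_EFFECTS))
    change_resid_sd: float = 0.025
    binge_loading: float = 0.3
    ats_locus_noise_sd: float = 0.25
    ats_cutoff: float = ATS_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_corr is None:
            self.target_corr = default_target_corr()
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.target_corr.shape != (6, 6):
            raise GeneratorError("target_corr must be 6x6")
        if not np.allclose(self.target_corr, self.target_corr.T):
            raise GeneratorError("target_corr must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.target_corr)[0])
        if eigmin < -1e-10:
            raise GeneratorError(
                f"target_corr is not positive semi-definite (smallest eigenvalue {eigmin:.3e})"
            )
        if abs(sum(self.missingness) - 1.0) > 1e-9:
            raise GeneratorError("missingness probabilities must sum to 1")
        if any(p < 0 for p in self.missingness):
            raise GeneratorError("missingness probabilities must be non-negative")
        if any(s <= 0 for s in self.sds.values()):
            raise GeneratorError("score SDs must be positive")
        if not 0.0 <= self.couple_icc < 1.0:
            raise GeneratorError("couple_icc must lie in [0, 1)")
        if self.mode not in ("correlation", "structural", "structural_change"):
            raise GeneratorError(f"unknown generator mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_corr"] = self.target_corr.tolist()
        d["waves"] = list(self.waves)
        d["missingness"] = list(self.missingness)
        return d


@dataclass
class CohortTruth:
    """Complete pre-missingness scores, the realized mask, and parameters."""

    complete: pd.DataFrame          # one row per person, all six scores + demographics
    mask: pd.DataFrame              # person_id x {w5, w6} participation booleans
    config: GeneratorConfig
    ats_reference: list             # per-locus (mean, sd) used for assay embedding
    n_individuals: int = 0
    n_person_waves: int = 0

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "ats_reference": [list(p) for p in self.ats_reference],
            "n_individuals": self.n_individuals,
            "n_person_waves": self.n_person_waves,
        }


def _mvn_sqrt(r: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(r)
    vals = np.maximum(vals, 0.0)
    return vecs @ np.diag(np.sqrt(vals))


def _draw_couple_structured(rng, n_couples: int, r: np.ndarray, icc: float) -> np.ndarray:
    """Person-level latent vectors with marginal corr ``r`` and partner corr ``icc * r``."""
    k = r.shape[0]
    root = _mvn_sqrt(r)
    u_couple = rng.standard_normal((n_couples, k)) @ root.T
    u_person = rng.standard_normal((2 * n_couples, k)) @ root.T
    z = np.sqrt(icc) * np.repeat(u_couple, 2, axis=0) + np.sqrt(1.0 - icc) * u_person
    return z


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None):
    """Simulate one dyadic two-wave cohort.

    Returns ``(sample_sheet, observed_scores, truth)``: the long-format
    sample sheet restricted to observed person-waves (with per-locus ATS
    assay columns), the observed score table (panel-shaped: person_id,
    couple_id, wave, ats, eis, cri, elevated), and the
    :class:`CohortTruth` carrying the complete table and mask.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_c = cfg.n_couples
    n_i = 2 * n_c
    person_ids = [f"p{c:04d}{p}" for c in range(n_c) for p in "ab"]
    couple_ids = [f"c{c:04d}" for c in range(n_c) for _ in "ab"]

    age = rng.normal(cfg.age_mean, cfg.age_sd, n_i)
    sex = (rng.random(n_i) < cfg.p_female).astype(int)  # 1 = female

    mu = np.array([cfg.means[v] for v in SCORE_VARS])
    sd = np.array([cfg.sds[v] for v in SCORE_VARS])

    if cfg.mode == "correlation":
        z = _draw_couple_structured(rng, n_c, cfg.target_corr, cfg.couple_icc)
    else:
        # wave-5 block (ats5, eis5, cri5) keeps the couple structure
        r5 = cfg.target_corr[:3, :3]
        z5 = _draw_couple_structured(rng, n_c, r5, cfg.couple_icc)
        z = np.empty((n_i, 6))
        z[:, :3] = z5
        age_z = (age - cfg.age_mean) / cfg.age_sd
        sex_z = (sex - cfg.p_female) / np.sqrt(cfg.p_female * (1.0 - cfg.p_female))
        s_ats, s_eis, s_cri = (STABILITIES[t] for t in ("ats", "eis", "cri"))
        # ATS6 / EIS6 follow their stabilities around the wave-6 marginals
        z[:, 3] = s_ats * z5[:, 0] + np.sqrt(1 - s_ats**2) * rng.standard_normal(n_i)
        z[:, 4] = s_eis * z5[:, 1] + np.sqrt(1 - s_eis**2) * rng.standard_normal(n_i)
        if cfg.mode == "structural":
            eff = cfg.prediction_effects
            beta = np.array([eff.get("age", 0.0), eff.get("sex", 0.0),
                             eff.get("cri5", 0.0), eff.get("ats5", 0.0),
                             eff.get("eis5", 0.0)])
            # predictor correlation: age/sex independent of the scores
            r_pred = np.eye(5)
            r_pred[2:, 2:] = r5[[2, 0, 1]][:, [2, 0, 1]]  # order cri5, ats5, eis5
            explained = float(beta @ r_pred @ beta)
            if explained >= 1.0:
                raise GeneratorError(
                    f"prediction effects explain {explained:.3f} >= 1 of CRI6 variance"
                )
            lin = (beta[0] * age_z + beta[1] * sex_z + beta[2] * z5[:, 2]
                   + beta[3] * z5[:, 0] + beta[4] * z5[:, 1])
            z[:, 5] = lin + np.sqrt(1.0 - explained) * rng.standard_normal(n_i)
        else:  # structural_change: raw-coefficient model for the CRI difference
            eff = cfg.change_effects
            cri5 = mu[2] + sd[2] * z5[:, 2]
            d_ats = (mu[3] + sd[3] * z[:, 3]) - (mu[0] + sd[0] * z5[:, 0])
            d_eis = (mu[4] + sd[4] * z[:, 4]) - (mu[1] + sd[1] * z5[:, 1])
            d_cri = (eff.get("age40", 0.0) * (age - 40.0)
                     + eff.get("sex", 0.0) * sex
                     + eff.get("cri5", 0.0) * cri5
                     + eff.get("d_ats", 0.0) * d_ats
                     + eff.get("d_eis", 0.0) * d_eis
                     + cfg.change_resid_sd * rng.standard_normal(n_i))
            z[:, 5] = (cri5 + d_cri - mu[5]) / sd[5]

    scores = mu + sd * z  # n_i x 6, columns in SCORE_VARS order

    binge = (cfg.binge_loading * z[:, 0]
             + np.sqrt(max(1.0 - cfg.binge_loading**2, 0.0)) * rng.standard_normal(n_i))

    # participation pattern per person: both / wave-5 only / wave-6 only
    p_both, p_w5, p_w6 = cfg.missingness
    cat = rng.choice(3, size=n_i, p=[p_both, p_w5, p_w6])
    w5_present = cat != 2
    w6_present = cat != 1
    if cfg.mar_logistic_coef != 0.0:
        # MAR: among wave-5 participants, wave-6 dropout depends on ATS5
        base = p_w5 / (p_both + p_w5) if (p_both + p_w5) > 0 else 0.0
        logit = np.log(base / (1 - base)) if 0 < base < 1 else -np.inf
        p_drop = 1.0 / (1.0 + np.exp(-(logit + cfg.mar_logistic_coef * z[:, 0])))
        drop = rng.random(n_i) < p_drop
        w6_present = np.where(w5_present, ~drop, w6_present)

    complete = pd.DataFrame(
        {
            "person_id": person_ids,
            "couple_id": couple_ids,
            "age": age,
            "sex": sex,
            "binge": binge,
            **{v: scores[:, k] for k, v in enumerate(SCORE_VARS)},
        }
    )
    mask = pd.DataFrame(
        {"person_id": person_ids, "w5": w5_present, "w6": w6_present}
    )

    # per-locus assay values: deviations around ATS/4 summing to zero,
    # so scoring against the fixed reference (0, 1) recovers ATS exactly
    ats_reference = [(0.0, 1.0)] * 4

    def assay_rows(ats_vals):
        dev = rng.normal(0.0, cfg.ats_locus_noise_sd, (len(ats_vals), 4))
        dev -= dev.mean(axis=1, keepdims=True)
        return ats_vals[:, None] / 4.0 + dev

    sheet_rows, score_rows = [], []
    for wave, present, ats_col, eis_col, cri_col in (
        (5, w5_present, "ats5", "eis5", "cri5"),
        (6, w6_present, "ats6", "eis6", "cri6"),
    ):
        idx = np.flatnonzero(present)
        assay = assay_rows(scores[idx, SCORE_VARS.index(ats_col)])
        sheet = pd.DataFrame(
            {
                "person_id": [person_ids[i] for i in idx],
                "couple_id": [couple_ids[i] for i in idx],
                "wave": wave,
                "age": age[idx],
                "sex": sex[idx],
                "binge": np.where(wave == 5, binge[idx], np.nan),
                **{c: assay[:, k] for k, c in enumerate(ATS_ASSAY_COLUMNS)},
            }
        )
        sheet_rows.append(sheet)
        score_rows.append(
            pd.DataFrame(
                {
                    "person_id": sheet["person_id"],
                    "couple_id": sheet["couple_id"],
                    "wave": wave,
                    "ats": scores[idx, SCORE_VARS.index(ats_col)],
                    "eis": scores[idx, SCORE_VARS.index(eis_col)],
                    "cri": scores[idx, SCORE_VARS.index(cri_col)],
                }
            )
        )
    sample_sheet = pd.concat(sheet_rows, ignore_index=True).sort_values(
        ["person_id", "wave"], kind="stable", ignore_index=True
    )
    observed = pd.concat(score_rows, ignore_index=True).sort_values(
        ["person_id", "wave"], kind="stable", ignore_index=True
    )
    observed["elevated"] = classify_elevated(observed["ats"].to_numpy(), cfg.ats_cutoff)

    truth = CohortTruth(
        complete=complete,
        mask=mask,
        config=cfg,
        ats_reference=ats_reference,
        n_individuals=int((w5_present | w6_present).sum()),
        n_person_waves=int(w5_present.sum() + w6_present.sum()),
    )
    return sample_sheet, observed, truth


def embed_betas(
    scores: pd.DataFrame,
    wt: WeightTable,
    cfg: ScoreConfig | None = None,
    noise_sd: float = 0.5,
    cri_noise_sd: float = 0.01,
    ats_embed_scale: float = 0.02,
    seed: int = 0,
) -> BetaMatrix:
    """Construct a beta matrix whose scores reproduce a target score table.

    For each observation, M-values at the weight-table probes are the
    minimum-norm solution of ``w . M = eis`` plus null-space noise of SD
    ``noise_sd`` (so the weighted sum is exact), converted to betas by
    the inverse logit.  The six CRI probes are set to ``cri + delta``
    with per-observation deltas summing to zero, so their mean is the
    target CRI exactly when no [0, 1] clamping occurs.  The four ATS
    probes encode ``ats/4`` plus zero-sum deviations on a linear beta
    scale centered at 0.5; scoring them with the fixed per-locus
    reference ``(0.5, ats_embed_scale)`` recovers the target ATS
    exactly, and pooled-sample scoring recovers it up to an affine map
    (correlation 1).

    ``scores`` needs columns person_id, wave, eis (or eis_z), cri, ats.
    """
    cfg = cfg or ScoreConfig()
    rng = np.random.default_rng(seed)
    w = wt.coefficients
    if not np.any(w != 0.0):
        raise GeneratorError("all-zero weight table cannot encode an EIS")
    overlap = (set(wt.probes) & set(cfg.cri_probes)) | (set(wt.probes) & set(cfg.ats_probes))
    if overlap:
        raise GeneratorError(f"weight table shares probes with CRI/ATS loci: {sorted(overlap)}")

    eis_col = "eis" if "eis" in scores.columns else "eis_z"
    keys = [obs_key(p, int(wv)) for p, wv in zip(scores["person_id"], scores["wave"])]
    n = len(keys)
    eis = scores[eis_col].to_numpy(dtype=float)
    cri = scores["cri"].to_numpy(dtype=float)
    ats = scores["ats"].to_numpy(dtype=float)

    # EIS probes: minimum-norm M plus null-space noise
    ww = float(w @ w)
    m = np.outer(eis, w) / ww  # n x p
    noise = rng.normal(0.0, noise_sd, m.shape)
    noise -= np.outer(noise @ w / ww, w)  # project out the weight direction
    m += noise
    eis_betas = inverse_mvalue(m)

    # CRI probes: cri + zero-sum deltas
    delta = rng.normal(0.0, cri_noise_sd, (n, len(cfg.cri_probes)))
    delta -= delta.mean(axis=1, keepdims=True)
    cri_betas = cri[:, None] + delta
    n_clamped = int(((cri_betas < 0) | (cri_betas > 1)).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} CRI beta cells clamped to [0, 1]", stacklevel=2)
    cri_betas = np.clip(cri_betas, 0.0, 1.0)

    # ATS probes: linear beta encoding around 0.5
    dev = rng.normal(0.0, 0.25, (n, 4))
    dev -= dev.mean(axis=1, keepdims=True)
    ats_betas = 0.5 + ats_embed_scale * (ats[:, None] / 4.0 + dev)
    if ((ats_betas < 0) | (ats_betas > 1)).any():
        raise GeneratorError(
            "ATS beta encoding left [0, 1]; reduce ats_embed_scale or the ATS spread"
        )

    probes = list(wt.probes) + list(cfg.cri_probes) + list(cfg.ats_probes)
    values = np.hstack([eis_betas, cri_betas, ats_betas]).T  # probes x samples
    return BetaMatrix(probes, keys, values)


def to_person_wide(scores: pd.DataFrame, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot a long score table to one row per person.

    Produces columns couple_id, age, sex, binge, ats5, eis5, cri5, ats6,
    eis6, cri6 (NaN where a wave was not observed).  Demographics come
    from the wave-5 row when present, else wave 6.  ``sheet`` supplies
    age/sex/binge when the score table lacks them.
    """
    long = scores.copy()
    if "eis" not in long.columns and "eis_z" in long.columns:
        long = long.rename(columns={"eis_z": "eis"})
    if sheet is not None:
        demo_src = sheet[["person_id", "wave"]].copy()
        for c in ("age", "sex", "binge"):
            if c in sheet.columns and c not in long.columns:
                demo_src[c] = sheet[c]
        if demo_src.shape[1] > 2:
            long = long.merge(demo_src, on=["person_id", "wave"], how="left")

    score_cols = [v for v in ("ats", "eis", "cri") if v in long.columns]
    wide = long[["person_id", "couple_id"]].drop_duplicates("person_id")
    for w in (5, 6):
        sub = long.loc[long["wave"] == w, ["person_id", *score_cols]]
        sub = sub.rename(columns={v: f"{v}{w}" for v in score_cols})
        wide = wide.merge(sub, on="person_id", how="left")
    demo_cols = [c for c in ("age", "sex", "binge") if c in long.columns]
    if demo_cols:
        # first non-null per person, wave 5 preferred
        demo = long.sort_values("wave", kind="stable").groupby("person_id")[demo_cols].first()
        wide = wide.merge(demo, on="person_id", how="left")
    for c in ("age", "sex", "binge", "ats5", "eis5", "cri5", "ats6", "eis6", "cri6"):
        if c not in wide.columns:
            wide[c] = np.nan
    return wide.reset_index(drop=True)


def summarize_cohort(sheet: pd.DataFrame, scores: pd.DataFrame, cutoff: float = ATS_CUTOFF) -> dict:
    """Descriptive report: means, SDs, correlations, missingness, % elevated.

    Correlations are reported twice — pairwise-complete and FIML (EM on
    the person-wide table) — over the six score variables.  Pattern
    counts (both / wave-5 only / wave-6 only) sum to the number of
    individuals.
    """
    wide = to_person_wide(scores, sheet)
    svars = list(SCORE_VARS)
    block = wide[svars]

    have5 = block[["ats5", "eis5", "cri5"]].notna().any(axis=1)
    have6 = block[["ats6", "eis6", "cri6"]].notna().any(axis=1)
    counts = {
        "both": int((have5 & have6).sum()),
        "w5_only": int((have5 & ~have6).sum()),
        "w6_only": int((~have5 & have6).sum()),
    }
    fit = em_mvn(block)
    pairwise = block.corr(min_periods=2)
    pct_elevated = {
        f"w{w}": float((scores.loc[scores["wave"] == w, "ats"] > cutoff).mean())
        for w in sorted(scores["wave"].unique())
    }
    return {
        "n_individuals": int(len(wide)),
        "n_person_waves": int(len(scores)),
        "pattern_counts": counts,
        "means": {v: float(block[v].mean()) for v in svars},
        "sds": {v: float(block[v].std(ddof=1)) for v in svars},
        "fiml_means": dict(zip(svars, fit.mean.tolist())),
        "fiml_corr": pd.DataFrame(fit.corr, index=svars, columns=svars),
        "pairwise_corr": pairwise,
        "pct_elevated": pct_elevated,
        "fiml_converged": bool(fit.converged),
    }
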