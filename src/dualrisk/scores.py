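"""The three methylation indices: EIS, Cardiac Risk Index and Alcohol T-Score.

EIS (Epigenetic Inflammation Score)
    Beta values at CRP-associated CpGs are logit-transformed to M-values,
    M = log2(beta / (1 - beta)), multiplied by their effect-size
    coefficients from a published CRP epigenome-wide association study,
    summed per observation, and z-standardized over the scoring sample
    (mean 0, SD 1), so one unit is one standard deviation.

CRI (Cardiac Risk Index)
    The mean beta value across six coronary-heart-disease CpGs
    (cg03725309, cg12586707, cg04988978, cg17901584, cg21161138,
    cg12655112).  Lower methylation indicates greater cardiac risk; the
    index is reported in beta-fraction units and is never sign-flipped.

ATS (Alcohol T-Score)
    An unweighted sum of four per-locus z-scores from a
    methylation-sensitive digital PCR assay (cg02583484, cg04987734,
    cg09935388, cg04583842).  Values strictly greater than 2.35 classify
    an observation as showing elevated alcohol consumption.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, WeightTable, align_probes

logger = logging.getLogger(__name__)

CRI_PROBES = (
    "cg03725309",
    "cg12586707",
    "cg04988978",
    "cg17901584",
    "cg21161138",
    "cg12655112",
)
ATS_PROBES = ("cg02583484", "cg04987734", "cg09935388", "cg04583842")

#: Validated elevated-alcohol-use threshold on the ATS scale.
ATS_CUTOFF = 2.35


class ScoreError(ValueError):
    """A score cannot be computed from the given inputs."""


@dataclass
class ScoreConfig:
    """Locus lists, cutoff and numerical options for the three indices.

    Attributes
    ----------
    cri_probes, ats_probes : tuple of str
        The six cardiac-risk CpGs and the four alcohol-assay CpGs.
    ats_cutoff : float
        Elevated-use threshold; classification uses strict ``>``.
    beta_epsilon : float
        Betas are clamped to ``[eps, 1 - eps]`` before the logit, since
        normalized arrays can produce exact 0/1 where the transform is
        undefined.  Must lie in (0, 0.5).
    ats_reference : optional sequence of (mean, sd) pairs
        External per-locus calibration for the ATS z-scores; when None
        the pooled scoring sample provides the per-locus mean/SD.
    cri_strict : bool
        Require all six CRI probes (otherwise the mean of those present
        is used and the count recorded).
    eis_per_wave_z : bool
        Z-standardize the EIS within each wave instead of pooled across
        waves.  Pooling (default) preserves between-wave change.
    """

    cri_probes: tuple = CRI_PROBES
    ats_probes: tuple = ATS_PROBES
    ats_cutoff: float = ATS_CUTOFF
    beta_epsilon: float = 1e-6
    ats_reference: list | None = None
    cri_strict: bool = False
    eis_per_wave_z: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.beta_epsilon < 0.5:
            raise ValueError("beta_epsilon must lie in (0, 0.5)")
        if not np.isfinite(self.ats_cutoff):
            raise ValueError("ats_cutoff must be finite")


def mvalue(beta, epsilon: float = 1e-6):
    """Logit-transform beta fractions to M-values, log2(b / (1 - b)).

    Betas are clamped to ``[epsilon, 1 - epsilon]`` first.  The transform
    is strictly increasing and antisymmetric about beta = 0.5
    (``mvalue(b) == -mvalue(1 - b)``).  NaN propagates.

    Raises
    ------
    ScoreError
        If any finite value lies outside [0, 1].
    """
    b = np.asarray(beta, dtype=float)
    finite = b[np.isfinite(b)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ScoreError("beta value outside [0, 1]")
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    c = np.clip(b, epsilon, 1.0 - epsilon)
    out = np.log2(c / (1.0 - c))
    if np.isscalar(beta):
        return float(out)
    return out


def inverse_mvalue(m):
    """Map M-values back to beta fractions, b = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


def compute_eis(
    bm: BetaMatrix,
    wt: WeightTable,
    cfg: ScoreConfig | None = None,
    waves: np.ndarray | None = None,
) -> pd.DataFrame:
    """EWAS-weighted inflammation score per observation.

    For observation *i*, ``eis_raw_i = sum_j w_j * M(beta_ij)`` over the
    probes shared between the matrix and the weight table; probes with a
    missing beta for an observation are dropped from that observation's
    sum.  ``eis_z`` standardizes the raw composite over the scoring
    sample (sample SD, n-1 denominator) — pooled across waves unless
    ``cfg.eis_per_wave_z`` and ``waves`` are given.

    Returns a DataFrame indexed by sample id with columns
    ``eis_raw``, ``eis_z``, ``eis_coverage``.
    """
    cfg = cfg or ScoreConfig()
    aligned, report = align_probes(bm, wt)
    if report["fraction"] < 0.95:
        warnings.warn(
            f"EIS probe coverage {report['fraction']:.3f} below 0.95 "
            f"({report['n_found']}/{report['n_requested']} probes found)",
            stacklevel=2,
        )
    n_obs = len(aligned.sample_ids)
    if n_obs < 2:
        raise ScoreError("cannot z-standardize the EIS with fewer than 2 observations")
    w = np.array([wt.entries[p] for p in aligned.probe_ids])
    m = mvalue(aligned.values, cfg.beta_epsilon)  # probes x samples
    present = np.isfinite(m)
    raw = np.nansum(w[:, None] * np.where(present, m, 0.0), axis=0)
    coverage = present.sum(axis=0) / report["n_requested"]

    z = np.empty_like(raw)
    if cfg.eis_per_wave_z and waves is not None:
        waves = np.asarray(waves)
        for wv in np.unique(waves):
            sel = waves == wv
            z[sel] = _zscore(raw[sel])
    else:
        z = _zscore(raw)
    return pd.DataFrame(
        {"eis_raw": raw, "eis_z": z, "eis_coverage": coverage},
        index=pd.Index(aligned.sample_ids, name="sample_id"),
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    if x.size < 2:
        raise ScoreError("cannot z-standardize fewer than 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ScoreError("zero standard deviation: all raw scores identical")
    return (x - x.mean()) / sd


def compute_cri(bm: BetaMatrix, cfg: ScoreConfig | None = None) -> pd.DataFrame:
    """Mean beta across the six cardiac-risk CpGs, per observation.

    Probes absent from the matrix (or missing for an observation) are
    skipped unless ``cfg.cri_strict``, in which case all six are
    required.  Lower values indicate greater risk.

    Returns a DataFrame with columns ``cri``, ``n_cri_probes_used``.
    """
    cfg = cfg or ScoreConfig()
    have = [p for p in cfg.cri_probes if p in bm.probe_ids]
    if not have:
        raise ScoreError("none of the cardiac-risk probes present in the beta matrix")
    if cfg.cri_strict and len(have) < len(cfg.cri_probes):
        missing = sorted(set(cfg.cri_probes) - set(have))
        raise ScoreError(f"strict CRI requires all six probes; missing {missing}")
    sub = bm.subset_probes(have)
    present = np.isfinite(sub.values)
    n_used = present.sum(axis=0)
    if cfg.cri_strict and (n_used < len(cfg.cri_probes)).any():
        raise ScoreError("strict CRI requires all six probes observed in every sample")
    if (n_used == 0).any():
        raise ScoreError("an observation has no cardiac-risk probe observed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cri = np.nanmean(sub.values, axis=0)
        # a constant probe set yields that constant exactly (no float drift)
        cmin, cmax = np.nanmin(sub.values, axis=0), np.nanmax(sub.values, axis=0)
    cri = np.where(cmin == cmax, cmin, cri)
    return pd.DataFrame(
        {"cri": cri, "n_cri_probes_used": n_used},
        index=pd.Index(bm.sample_ids, name="sample_id"),
    )


def compute_ats(values, reference=None) -> np.ndarray:
    """Alcohol T-Score: unweighted sum of four per-locus z-scores.

    Parameters
    ----------
    values : array-like, shape (n_obs, 4)
        Per-locus assay values; the assay is a fixed 4-plex, so any
        missing locus value is an error (no partial ATS).
    reference : sequence of 4 (mean, sd) pairs, optional
        External calibration.  When None, each locus is z-scored against
        the pooled scoring sample (mean/SD over observations, sample SD).
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[1] != 4:
        raise ScoreError(f"ATS assay is a 4-plex; got {x.shape[1]} loci")
    if not np.all(np.isfinite(x)):
        raise ScoreError("missing or non-finite ATS locus value (no partial ATS)")
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (4, 2):
            raise ScoreError("ATS reference must be four (mean, sd) pairs")
        mu, sd = ref[:, 0], ref[:, 1]
    else:
        if x.shape[0] < 2:
            raise ScoreError("pooled ATS reference needs at least 2 observations")
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ScoreError("ATS reference SDs must be positive")
    ats = ((x - mu) / sd).sum(axis=1)
    return ats if np.asarray(values).ndim == 2 else float(ats[0])


def classify_elevated(ats, cutoff: float = ATS_CUTOFF):
    """True where the ATS strictly exceeds the elevated-use cutoff."""
    a = np.asarray(ats, dtype=float)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = a > cutoff
    return bool(out) if out.ndim == 0 else out


def score_cohort(
    bm: BetaMatrix,
    wt: WeightTable,
    sheet: pd.DataFrame,
    cfg: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Compute all three indices for every person-wave in a sample sheet.

    Observations are matched by the ``"<person>@<wave>"`` key.  ATS comes
    from the sheet's per-locus assay columns (``ats1..ats4``) when
    present, otherwise from the four ATS probes of the beta matrix.
    Returns the scored panel: person_id, couple_id, wave, eis_raw, eis_z,
    cri, ats, elevated, eis_coverage, n_cri_probes_used.
    """
    from .io import ATS_ASSAY_COLUMNS, obs_key

    cfg = cfg or ScoreConfig()
    keys = [obs_key(p, w) for p, w in zip(sheet["person_id"], sheet["wave"])]
    missing = [k for k in keys if k not in bm.sample_ids]
    if missing:
        raise ScoreError(f"sample sheet rows absent from beta matrix: {missing[:5]} ...")
    col = {s: j for j, s in enumerate(bm.sample_ids)}
    order = [col[k] for k in keys]
    sub = BetaMatrix(list(bm.probe_ids), keys, bm.values[:, order])

    waves = sheet["wave"].to_numpy()
    eis = compute_eis(sub, wt, cfg, waves=waves)
    cri = compute_cri(sub, cfg)

    if all(c in sheet.columns for c in ATS_ASSAY_COLUMNS) and (
        sheet[ATS_ASSAY_COLUMNS].notna().all(axis=None)
    ):
        assay = sheet[ATS_ASSAY_COLUMNS].to_numpy(dtype=float)
    else:
        have = [p for p in cfg.ats_probes if p in sub.probe_ids]
        if len(have) < 4:
            raise ScoreError(
                "ATS requires either assay columns ats1..ats4 in the sample sheet "
                "or all four ATS probes in the beta matrix"
            )
        assay = sub.subset_probes(list(cfg.ats_probes)).values.T
    ats = compute_ats(assay, reference=cfg.ats_reference)

    panel = pd.DataFrame(
        {
            "person_id": sheet["person_id"].to_numpy(),
            "couple_id": sheet["couple_id"].to_numpy(),
            "wave": waves,
            "eis_raw": eis["eis_raw"].to_numpy(),
            "eis_z": eis["eis_z"].to_numpy(),
            "cri": cri["cri"].to_numpy(),
            "ats": ats,
            "elevated": classify_elevated(ats, cfg.ats_cutoff),
            "eis_coverage": eis["eis_coverage"].to_numpy(),
            "n_cri_probes_used": cri["n_cri_probes_used"].to_numpy(),
        }
    )
    return panel
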