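"""Cohort-level statistics on per-muscle visual scores and fat fractions.

Covers the analyses run on a cohort of scored muscle MRIs: k-means
clustering of patients into imaging patterns, left/right asymmetry and
STIR-hyperintensity summaries, intraclass-correlation reproducibility of
repeated measurements, Student's t-test, Spearman correlation with
Bonferroni correction, and the linear-vs-logarithmic R² comparison between
mean visual score and intramuscular fat fraction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._kmeans import lloyd_kmeans
from .errors import DegenerateInputError, InvalidParameterError
from .phantom import LEG_MUSCLES, THIGH_MUSCLES


@dataclass
class ClusterResult:
    assignments: np.ndarray      # (n_patients,) cluster ids 1..k, 1 = mildest
    centers: np.ndarray          # (k, n_muscles) mean score vectors
    inertia: float
    n_iter: int
    muscles: list[str]
    patient_ids: list[str]


def region_muscles(region: str) -> list[str]:
    try:
        return {"thigh": THIGH_MUSCLES, "leg": LEG_MUSCLES}[region]
    except KeyError:
        raise InvalidParameterError(f"unknown region {region!r}") from None


def side_mean_features(table: pd.DataFrame, region: str = "thigh") -> pd.DataFrame:
    """Per-patient feature vectors: each muscle's grade averaged over the
    two sides.  Thigh and leg regions are featurized separately."""
    muscles = region_muscles(region)
    feats = {}
    for m in muscles:
        feats[m] = (table[f"{m}_L"].astype(float) + table[f"{m}_R"].astype(float)) / 2.0
    return pd.DataFrame(feats, index=table.index)


def cluster_patients(
    table: pd.DataFrame,
    region: str = "thigh",
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """k-means clustering of patients into imaging patterns.

    Features are the side-averaged per-muscle grades of one limb region.
    Lloyd iteration (assign to nearest center / recompute centers), best of
    ``n_restarts`` by inertia; final cluster labels are renumbered so that
    cluster 1 has the lowest overall mean score (mildest pattern).
    """
    X = side_mean_features(table, region).to_numpy(dtype=float)
    if k > len(X):
        raise InvalidParameterError(
            f"k={k} exceeds the {len(X)} available patients"
        )
    res = lloyd_kmeans(X, k, n_restarts=n_restarts, seed=seed)
    severity = res.centers.mean(axis=1)
    order = np.argsort(severity, kind="stable")
    renum = np.empty(k, dtype=int)
    renum[order] = np.arange(1, k + 1)
    ids = (
        table["patient_id"].astype(str).tolist()
        if "patient_id" in table
        else [str(i) for i in table.index]
    )
    return ClusterResult(
        assignments=renum[res.labels],
        centers=res.centers[order],
        inertia=res.inertia,
        n_iter=res.n_iter,
        muscles=region_muscles(region),
        patient_ids=ids,
    )


# --------------------------------------------------------------------------


def asymmetry_summary(table: pd.DataFrame) -> dict:
    """Left/right asymmetry: a muscle pair is asymmetric when the two
    sides differ by at least one grade; a patient is asymmetric in a limb
    region when any muscle pair of that region is asymmetric.

    Returns per-muscle asymmetry frequencies (percent of patients) and the
    cohort percentage of patients with any asymmetric thigh / leg muscle.
    """
    per_muscle: dict[str, float] = {}
    region_any = {}
    for region, muscles in (("thigh", THIGH_MUSCLES), ("leg", LEG_MUSCLES)):
        present = [m for m in muscles if f"{m}_L" in table and f"{m}_R" in table]
        if not present:
            continue
        asym = pd.DataFrame(
            {
                m: (table[f"{m}_L"] - table[f"{m}_R"]).abs() >= 1
                for m in present
            }
        )
        for m in present:
            per_muscle[m] = 100.0 * float(asym[m].mean())
        region_any[region] = asym.any(axis=1)
    return {
        "per_muscle_percent": per_muscle,
        "patient_any_thigh": region_any.get("thigh"),
        "patient_any_leg": region_any.get("leg"),
        "percent_patients_thigh": (
            100.0 * float(region_any["thigh"].mean()) if "thigh" in region_any else None
        ),
        "percent_patients_leg": (
            100.0 * float(region_any["leg"].mean()) if "leg" in region_any else None
        ),
    }


def stir_frequency(table: pd.DataFrame) -> tuple[float, float]:
    """Percent of muscle entries with a STIR hyperintensity flag, and
    percent of patients with at least one flagged muscle."""
    stir_cols = [c for c in table.columns if c.startswith("stir_")]
    if not stir_cols:
        raise InvalidParameterError("table has no stir_* columns")
    flags = table[stir_cols].to_numpy(dtype=int)
    pct_muscles = 100.0 * flags.mean()
    pct_patients = 100.0 * float((flags.sum(axis=1) > 0).mean())
    return float(pct_muscles), pct_patients


# --------------------------------------------------------------------------


def icc_agreement(ratings: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Two-way random-effects, absolute-agreement, single-measure ICC —
    ICC(2,1) — plus per-subject coefficients of variation.

    ``ratings`` is a complete subjects × raters matrix.  The ICC comes from
    the standard mean-squares decomposition

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with MSR/MSC/MSE the rows (subjects), columns (raters) and error mean
    squares.  CV per subject is sd/mean of that subject's ratings in
    percent; returned as (mean, sd) over subjects.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise DegenerateInputError("need >= 2 subjects and >= 2 raters")
    if np.isnan(R).any():
        raise DegenerateInputError("ratings matrix must be complete")
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateInputError(
            "zero between-subject variance and zero error: ICC undefined"
        )
    icc = (msr - mse) / denom

    means = row_means
    sds = R.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, 100.0 * sds / np.abs(means), np.nan)
    return float(icc), (float(np.nanmean(cv)), float(np.nanstd(cv, ddof=1)))


def icc_consistency(ratings: np.ndarray) -> float:
    """Two-way mixed, consistency, single-measure ICC — ICC(3,1).
    Ignores systematic rater offsets; used for comparison with the
    absolute-agreement form."""
    R = np.asarray(ratings, dtype=float)
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((R - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))


# --------------------------------------------------------------------------


def _midranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_bonferroni(
    x: np.ndarray, y: np.ndarray, m_tests: int = 1
) -> tuple[float, float, float]:
    """Spearman rank correlation with Bonferroni-adjusted p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    For n ≤ 10 the p-value is computed by exhaustive enumeration of all n!
    permutations (two-sided: fraction of permutations with |rho| at least
    as extreme); for larger n the standard t approximation with n − 2
    degrees of freedom is used.  The adjusted p is min(1, m_tests · p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise InvalidParameterError("need equal-length vectors with n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("constant vector: correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 10:
        p_raw = _exact_spearman_p(rx, ry, rho)
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p_raw = float(2.0 * stats.t.sf(abs(t), n - 2))
        p_raw = min(1.0, p_raw)
    return rho, p_raw, min(1.0, m_tests * p_raw)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of y-orderings."""
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    sx, sy = rx.std(), ry.std()
    thresh = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    it = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(it, 200_000))
        if not chunk:
            break
        idx = np.asarray(chunk, dtype=np.int8)
        cov = (ry[idx] @ rx) / n - mx * my
        rhos = cov / (sx * sy)
        hits += int(np.sum(np.abs(rhos) >= thresh))
        total += len(chunk)
    return hits / total


def two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample Student's t-test (two-sided).

    Returns (t, df, p).  Raises on zero pooled variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise DegenerateInputError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def linear_vs_log_r2(
    mean_score: np.ndarray, fraction: np.ndarray
) -> tuple[float, float]:
    """R² of the fat fraction regressed on the mean visual score, on the
    linear and on the logarithmic scale.

    A markedly higher log-scale R² indicates the exponential-like growth of
    fat infiltration with the ordinal visual grade (and the visual scale's
    ceiling at high infiltration).  Zero fractions are offset by half the
    smallest positive fraction before taking the log, with a warning.
    """
    s = np.asarray(mean_score, dtype=float)
    f = np.asarray(fraction, dtype=float)
    if np.unique(s).size < 2:
        raise DegenerateInputError("all scores equal: fit undefined")
    if (f < 0).any():
        raise InvalidParameterError("fat fractions must be >= 0")
    r2_lin = _r2(s, f)
    fz = f.copy()
    if (fz == 0).any():
        pos = fz[fz > 0]
        if pos.size == 0:
            raise DegenerateInputError("all fractions zero: log fit undefined")
        warnings.warn(
            "zero fat fractions offset by half the smallest positive value "
            "for the log fit",
            stacklevel=2,
        )
        fz[fz == 0] = pos.min() / 2.0
    r2_log = _r2(s, np.log(fz))
    return r2_lin, r2_log


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
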