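"""Associations between shape-mode loadings and clinical indices.

Each clinical index is tested univariately against each retained shape
mode with Spearman's rho, Kendall's tau-b and Pearson's r, and against
the joint block of the first five modes with canonical correlation
analysis (with a single clinical variable, the first canonical
correlation equals the multiple correlation of that variable on the
loadings).  Binary and ordinal indices enter numerically; the
rank-based tests make this defensible.

For very small samples (n <= 8) the rank-test p-values are computed
exactly by enumerating all n! permutations of one variable; above that
the standard large-sample approximations are used.  The significance
gate is p < 0.05 and — deliberately, as an exploratory screen — no
multiple-testing correction is applied; the output metadata records
the p-values as uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, JoinError, UndefinedCorrelationError

SIGNIFICANCE_LEVEL = 0.05
_EXACT_N = 8  # full-permutation enumeration up to this sample size


@dataclass(frozen=True)
class AssociationResult:
    """One correlation estimate with its two-sided p-value."""

    index_name: str
    statistic_name: str  # rho | tau_b | r | canonical_R
    estimate: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def _as_float_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need n >= 3 observations")
    return x, y


def pearson_r(x, y, index_name: str = "") -> AssociationResult:
    """Pearson product-moment correlation, p from t with n-2 df."""
    x, y = _as_float_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("Pearson r undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(index_name, "r", float(r), float(p), x.size)


def _exact_rank_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p for the rank correlation of (rx, ry)."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    observed = abs(rxc @ ryc) / denom
    perms = np.array(list(permutations(range(rx.size))))
    stats_all = np.abs(ryc[perms] @ rxc) / denom
    return float(np.mean(stats_all >= observed - 1e-12))


def spearman_rho(x, y, index_name: str = "") -> AssociationResult:
    """Spearman rank correlation (mid-ranks for ties).

    The p-value is exact by full permutation enumeration for n <= 8 and
    the usual t-approximation otherwise.
    """
    x, y = _as_float_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("Spearman rho undefined for constant input")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry)[0])
    if x.size <= _EXACT_N:
        p = _exact_rank_p(rx, ry)
    else:
        p = float(stats.spearmanr(x, y)[1])
    return AssociationResult(index_name, "rho", rho, p, x.size)


def _tau_b_numerator_denominator(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(C - D, sqrt((n0-n1)(n0-n2))) by explicit pair enumeration."""
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    num = float(np.sum(sx[iu] * sy[iu]))
    n0 = n * (n - 1) / 2
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    n1 = float(np.sum(cx * (cx - 1) / 2))
    n2 = float(np.sum(cy * (cy - 1) / 2))
    return num, float(np.sqrt((n0 - n1) * (n0 - n2)))


def kendall_tau_b(x, y, index_name: str = "") -> AssociationResult:
    """Kendall's tau-b with tie correction.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)).  The p-value is exact
    by permutation enumeration for n <= 8, otherwise the normal
    approximation with tie-corrected variance.
    """
    x, y = _as_float_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "tau_b undefined when all pairs are tied in one variable"
        )
    num, denom = _tau_b_numerator_denominator(x, y)
    tau = num / denom
    n = x.size
    if n <= _EXACT_N:
        sy = np.sign(y[:, None] - y[None, :])
        sx = np.sign(x[:, None] - x[None, :])
        iu, ju = np.triu_indices(n, k=1)
        perms = np.array(list(permutations(range(n))))
        nums = np.zeros(perms.shape[0])
        for i, j in zip(iu, ju):
            nums += sx[i, j] * sy[perms[:, i], perms[:, j]]
        p = float(np.mean(np.abs(nums) >= abs(num) - 1e-12))
    else:
        p = float(stats.kendalltau(x, y, variant="b")[1])
    return AssociationResult(index_name, "tau_b", float(tau), p, n)


def cca_modes_vs_index(
    loadings: np.ndarray, index, index_name: str = ""
) -> AssociationResult:
    """First canonical correlation of a mode block with one clinical index.

    With a single clinical variable this is the multiple correlation R
    of regressing the index on the loadings; the p-value is the overall
    regression F-test (the single-response reduction of Rao's F
    approximation to Wilks' lambda).  Rank-deficient loading blocks
    have their dependent columns dropped with a warning.
    """
    L = np.asarray(loadings, dtype=np.float64)
    y = np.asarray(index, dtype=np.float64)
    if L.ndim != 2 or L.shape[0] != y.size:
        raise InvalidArgumentError("loadings must be (n, m) matching the index")
    n = y.size
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("index is constant")
    Lc = L - L.mean(axis=0)
    rank = np.linalg.matrix_rank(Lc)
    if rank < Lc.shape[1]:
        warnings.warn(
            f"loading block is rank deficient ({rank} < {Lc.shape[1]}); "
            "dependent columns carry no extra degrees of freedom",
            stacklevel=2,
        )
    q = rank  # effective predictors; lstsq handles the deficiency itself
    if n <= q + 2:
        raise InvalidArgumentError(f"need n > m + 2 subjects (n={n}, m={q})")
    yc = y - y.mean()
    coef, _, _, _ = np.linalg.lstsq(Lc, yc, rcond=None)
    fitted = Lc @ coef
    ss_res = float(np.sum((yc - fitted) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    if r2 >= 1.0:
        p = 0.0
    else:
        f_stat = (r2 / q) / ((1.0 - r2) / (n - q - 1))
        p = float(stats.f.sf(f_stat, q, n - q - 1))
    return AssociationResult(index_name, "canonical_R", float(np.sqrt(r2)), p, n)


def association_screen(
    loadings: np.ndarray,
    clinical: pd.DataFrame,
    tests: tuple[str, ...] = ("rho", "tau_b", "r"),
    indices: tuple[str, ...] | None = None,
    n_modes: int | None = None,
    include_cca: bool = True,
    subject_ids: tuple | None = None,
) -> pd.DataFrame:
    """Univariate screen of every (clinical index, mode, test) triple.

    Returns a table with columns ``index, test, target, estimate,
    p_value, n, significant``; ``target`` is ``mode_k`` (1-based) or
    ``cca`` for the joint canonical correlation.  Indices that are
    constant in this sample yield NaN estimates flagged non-significant.
    P-values are uncorrected for multiple testing (recorded in
    ``DataFrame.attrs``).
    """
    test_fns = {"rho": spearman_rho, "tau_b": kendall_tau_b, "r": pearson_r}
    unknown = set(tests) - set(test_fns)
    if unknown:
        raise InvalidArgumentError(f"unknown tests {sorted(unknown)}")
    L = np.asarray(loadings, dtype=np.float64)
    if subject_ids is not None:
        if "subject_id" not in clinical.columns:
            raise JoinError("clinical table has no subject_id column to join on")
        clinical = clinical.set_index("subject_id")
        missing = [s for s in subject_ids if s not in clinical.index]
        if missing:
            raise JoinError(f"subjects missing from clinical table: {missing}")
        clinical = clinical.loc[list(subject_ids)].reset_index()
    elif len(clinical) != L.shape[0]:
        raise JoinError(
            f"{L.shape[0]} subjects but {len(clinical)} clinical records"
        )
    if indices is None:
        indices = tuple(
            c for c in clinical.columns if c not in ("subject_id", "group")
        )
    m = L.shape[1] if n_modes is None else min(n_modes, L.shape[1])

    rows = []
    for index_name in indices:
        y = clinical[index_name].to_numpy(dtype=np.float64)
        for k in range(m):
            for test in tests:
                try:
                    res = test_fns[test](L[:, k], y, index_name)
                    est, p = res.estimate, res.p_value
                except UndefinedCorrelationError:
                    est, p = np.nan, np.nan
                rows.append(
                    {
                        "index": index_name,
                        "test": test,
                        "target": f"mode_{k + 1}",
                        "estimate": est,
                        "p_value": p,
                        "n": len(y),
                        "significant": bool(p < SIGNIFICANCE_LEVEL)
                        if np.isfinite(p)
                        else False,
                    }
                )
        if include_cca:
            try:
                res = cca_modes_vs_index(L[:, :m], y, index_name)
                est, p = res.estimate, res.p_value
            except UndefinedCorrelationError:
                est, p = np.nan, np.nan
            rows.append(
                {
                    "index": index_name,
                    "test": "cca",
                    "target": "cca",
                    "estimate": est,
                    "p_value": p,
                    "n": len(y),
                    "significant": bool(p < SIGNIFICANCE_LEVEL)
                    if np.isfinite(p)
                    else False,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["multiple_testing_correction"] = "none (uncorrected p-values)"
    out.attrs["significance_level"] = SIGNIFICANCE_LEVEL
    return out
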