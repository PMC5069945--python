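"""PCA point-distribution model of bi-ventricular shape.

Aligned meshes are stacked as rows of concatenated vertex coordinates
(LV endo | LV epi | RV endo) and decomposed about the population mean.
Because the coordinate dimension (3V, thousands) vastly exceeds the
cohort size (tens), the decomposition is done in the dual: the n x n
Gram matrix of centred rows is eigen-decomposed and the eigenvectors
mapped back to coordinate space.  This is exact and memory-light.

Loadings are expressed in SD units — a loading of 1 means the subject
sits one population standard deviation from the mean along that mode —
so "shape at +/-1 SD" visualisations and per-subject scores read
directly off the loading matrix.  Mode signs are arbitrary in PCA; the
convention here makes each mode's largest-magnitude coordinate
positive.

The number of modes retained for downstream analysis is the smallest
count whose cumulative variance fraction reaches a threshold (default
80 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateControlError,
    DegeneratePopulationError,
    IncompatiblePopulationError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .mesh import BiVentricleMesh, check_shared_topology

#: Relative eigenvalue threshold below which a mode counts as numerically zero.
_EIG_TOL = 1e-12


@dataclass(frozen=True)
class ShapePopulation:
    """Stacked population: one row of concatenated coordinates per subject."""

    matrix: np.ndarray  # (n, 3V)
    subject_ids: tuple
    phase: str
    surface_slices: dict  # surface name -> slice into the row vector
    template: BiVentricleMesh  # topology reference for rebuilding meshes

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ShapeModeSet:
    """Mean shape, orthonormal shape modes and their variances."""

    mean: np.ndarray            # (3V,)
    modes: np.ndarray           # (3V, m), orthonormal columns
    variances: np.ndarray       # (m,), mm^2, descending
    variance_fractions: np.ndarray  # (m,), sums to 1 over computable modes
    surface_slices: dict
    template: BiVentricleMesh

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def build_population(
    meshes: list[BiVentricleMesh],
    phase: str = "ES",
    surfaces: tuple[str, ...] | None = None,
    subject_ids: tuple | None = None,
) -> ShapePopulation:
    """Stack aligned meshes into a population matrix.

    ``surfaces`` selects a subset (e.g. ``("rv_endo",)`` for a
    single-ventricle analysis); default is all three in the canonical
    order LV endo, LV epi, RV endo.
    """
    if not meshes:
        raise InsufficientDataError("empty population")
    check_shared_topology(meshes)
    names = surfaces if surfaces is not None else tuple(
        n for n, _ in meshes[0].surfaces()
    )
    slices: dict[str, slice] = {}
    start = 0
    for name in names:
        n_v = getattr(meshes[0], name).n_vertices
        slices[name] = slice(start, start + 3 * n_v)
        start += 3 * n_v
    rows = [
        np.concatenate([getattr(m, name).vertices.ravel() for name in names])
        for m in meshes
    ]
    ids = subject_ids if subject_ids is not None else tuple(range(len(meshes)))
    return ShapePopulation(
        matrix=np.asarray(rows),
        subject_ids=tuple(ids),
        phase=phase,
        surface_slices=slices,
        template=meshes[0],
    )


def fit_pca(pop: ShapePopulation) -> tuple[ShapeModeSet, np.ndarray]:
    """Fit the point-distribution model; returns (mode set, loadings).

    Dual PCA: eigen-decomposition of the centred Gram matrix, modes
    mapped back to coordinate space.  Variances are eigenvalues of the
    sample covariance (denominator n - 1); at most n - 1 modes carry
    variance.  Loadings are in SD units: training-population columns
    have mean 0 and sample SD 1.
    """
    n = pop.n_subjects
    if n < 3:
        raise InsufficientDataError("PCA needs >= 3 subjects")
    mean = pop.matrix.mean(axis=0)
    centred = pop.matrix - mean
    gram = centred @ centred.T
    trace = np.trace(gram)
    if trace <= 0:
        raise DegeneratePopulationError("population has zero total variance")
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > _EIG_TOL * trace
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]

    # map dual eigenvectors to coordinate-space modes: v_j = C^T u_j / s_j
    modes = centred.T @ (eigvecs / np.sqrt(eigvals))
    variances = eigvals / (n - 1)
    loadings = eigvecs * np.sqrt(n - 1)  # = C v / sqrt(variance)

    # sign convention: largest-magnitude coordinate of each mode positive
    flip = np.sign(
        modes[np.argmax(np.abs(modes), axis=0), np.arange(modes.shape[1])]
    )
    modes *= flip
    loadings *= flip

    mode_set = ShapeModeSet(
        mean=mean,
        modes=modes,
        variances=variances,
        variance_fractions=eigvals / eigvals.sum(),
        surface_slices=pop.surface_slices,
        template=pop.template,
    )
    return mode_set, loadings


def n_modes_for_variance(modes: ShapeModeSet, threshold: float = 0.8) -> int:
    """Smallest mode count whose cumulative variance fraction reaches threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise InvalidArgumentError("threshold must be in [0, 1]")
    if threshold == 0.0:
        return 0
    cum = np.cumsum(modes.variance_fractions)
    # guard against round-off at threshold 1.0
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def project_subject(
    mesh: BiVentricleMesh, modes: ShapeModeSet
) -> tuple[np.ndarray, np.ndarray]:
    """Project a new (aligned, template-topology) subject onto the modes.

    Returns the loading vector in SD units and the residual coordinate
    vector orthogonal to the mode subspace.
    """
    x = np.concatenate(
        [
            getattr(mesh, name).vertices.ravel()
            for name in modes.surface_slices
        ]
    )
    if x.size != modes.mean.size:
        raise IncompatiblePopulationError(
            "subject does not match the model's coordinate dimension"
        )
    centred = x - modes.mean
    raw = modes.modes.T @ centred
    loadings = raw / np.sqrt(modes.variances)
    residual = centred - modes.modes @ raw
    return loadings, residual


def mode_at_sd(modes: ShapeModeSet, k: int, s: float) -> BiVentricleMesh:
    """Mesh at ``s`` standard deviations along mode ``k`` (1-based)."""
    if not 1 <= k <= modes.n_modes:
        raise InvalidArgumentError(
            f"mode index {k} out of range 1..{modes.n_modes}"
        )
    flat = modes.mean + s * np.sqrt(modes.variances[k - 1]) * modes.modes[:, k - 1]
    # rebuild through the stored topology reference
    template = modes.template
    parts = {}
    for name, sl in modes.surface_slices.items():
        parts[name] = getattr(template, name).with_vertices(
            flat[sl].reshape(-1, 3)
        )
    missing = {n for n, _ in template.surfaces()} - set(parts)
    for name in missing:  # single-ventricle model: carry template surfaces
        parts[name] = getattr(template, name)
        warnings.warn(
            f"surface {name!r} not in the model; template surface carried over",
            stacklevel=2,
        )
    return BiVentricleMesh(phase_label=template.phase_label, **parts)


def control_loading_stats(control_loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode mean and SD of the control group's loadings."""
    arr = np.asarray(control_loadings, dtype=np.float64)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateControlError("control group has zero spread on a mode")
    return mu, sd


def summed_loading_score(
    loadings_subject: np.ndarray,
    control_stats: tuple[np.ndarray, np.ndarray],
    variance_fractions: np.ndarray,
    n_modes: int = 5,
) -> float:
    """Scalar regional shape-abnormality score from the first modes.

    Each of the first ``n_modes`` loadings is z-normalised against the
    control group, taken in absolute value (mode signs are arbitrary),
    scaled by the mode's variance fraction and summed:

        score = sum_k vf_k * |(l_k - mu_k^ctrl) / sd_k^ctrl|

    A subject at the control mean scores 0; larger scores mean more
    abnormal shape, weighted toward the population's dominant modes.
    """
    mu, sd = control_stats
    m = n_modes
    if len(loadings_subject) < m or len(mu) < m or len(variance_fractions) < m:
        raise InvalidArgumentError(f"need at least {m} modes for the score")
    if np.any(np.asarray(sd[:m]) <= 0):
        raise DegenerateControlError("control SD must be positive")
    z = np.abs((np.asarray(loadings_subject)[:m] - mu[:m]) / sd[:m])
    return float(np.sum(variance_fractions[:m] * z))


def loo_summed_scores(
    control_loadings: np.ndarray,
    case_loadings: np.ndarray,
    variance_fractions: np.ndarray,
    n_modes: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed scores under a leave-one-out protocol.

    Each control subject is scored against statistics from the other
    controls (so it never normalises itself); each case subject is
    scored against the full control group.  Returns
    ``(control_scores, case_scores)``.
    """
    ctrl = np.asarray(control_loadings, dtype=np.float64)
    if ctrl.shape[0] < 3:
        raise InsufficientDataError("need >= 3 controls for LOO statistics")
    control_scores = np.empty(ctrl.shape[0])
    for i in range(ctrl.shape[0]):
        others = np.delete(ctrl, i, axis=0)
        control_scores[i] = summed_loading_score(
            ctrl[i], control_loading_stats(others), variance_fractions, n_modes
        )
    full_stats = control_loading_stats(ctrl)
    case_scores = np.array(
        [
            summed_loading_score(row, full_stats, variance_fractions, n_modes)
            for row in np.asarray(case_loadings)
        ]
    )
    return control_scores, case_scores
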