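"""Synthetic bi-ventricular cohorts with planted shape-mode structure.

Real ARVC imaging cohorts cannot be redistributed, so every downstream
stage of the pipeline (alignment, PCA shape modelling, currents
distances, classification, clinical correlation) is exercised on
populations generated here.  The generator plants exactly five
orthonormal deformation modes on a stylised bi-ventricular template:

* ``dilation`` — global dilation/shrinking of both ventricles,
* ``rvot_elong`` — elongation/shortening at the RV outflow tract,
* ``septal_tilt`` — base-to-apex tilting of the RV septal wall,
* ``length`` — base-to-apex lengthening/shortening of both ventricles,
* ``inlet_outlet_bulge`` — bulging at both the RV inflow and outflow.

Default mode variance fractions are 44/15/10/7/5 % of total population
variance with a 19 % isotropic residual, so a correct PCA stage should
recover five dominant modes crossing the 80 % cumulative-variance mark.
Clinical indices are drawn stochastically from the planted loadings so
that association tests have known ground truth.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the cohort spec; identical spec + seed reproduces vertex arrays
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidArgumentError
from .mesh import BiVentricleMesh, build_ring_shell

MODE_IDS = ("dilation", "rvot_elong", "septal_tilt", "length", "inlet_outlet_bulge")

#: Default planted variance fractions (fraction of total population variance).
DEFAULT_MODE_VARIANCES = {
    "dilation": 0.44,
    "rvot_elong": 0.15,
    "septal_tilt": 0.10,
    "length": 0.07,
    "inlet_outlet_bulge": 0.05,
}
DEFAULT_RESIDUAL_NOISE_FRACTION = 0.19

#: Total population variance scale T (mm^2, in the flattened-coordinate norm).
DEFAULT_TOTAL_VARIANCE = 20000.0

# Template geometry (mm).  LV modelled as nested half-ellipsoids; RV as a
# laterally offset half-ellipsoid with a concave (crescent) septal side,
# an anterior outflow-tract bulge and an inferior inflow region.
_LV_ENDO_AXES = (25.0, 25.0, 75.0)
_LV_EPI_AXES = (33.0, 33.0, 82.0)
_RV_AXES = (32.0, 36.0, 66.0)
_RV_CENTER_X = 50.0
_RV_SEPTAL_INDENT = 0.5      # fractional radius indentation facing the LV
_RV_SEPTAL_WIDTH = 0.9       # rad, angular width of the indentation
_RVOT_PHI = 0.5 * np.pi      # anterior: outflow tract
_RV_INLET_PHI = 1.5 * np.pi  # inferior: inflow (tricuspid) region
_RVOT_BULGE = 0.30
_RVOT_PHI_WIDTH = 0.35       # rad
_RVOT_THETA_WIDTH = 0.25     # rad, concentrates the bulge near the base


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


def _capped_half_ellipsoid(
    axes: tuple[float, float, float],
    nc: int,
    na: int,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    radius_fn=None,
) -> Surface:
    """Closed half-ellipsoid: apex pole, ``na`` rings, flat basal cap.

    Vertex layout (shared by every surface and by :func:`loft-style
    reconstruction <bivshape.preprocess.loft_contours>`): index 0 is the
    apex pole, indices ``1 .. na*nc`` are the rings from apex to base,
    and the last index is the basal cap centre.  ``radius_fn(phi,
    theta)`` optionally modulates the in-plane radius (crescent,
    bulges).
    """
    a, b, c = axes
    cx, cy, cz = center
    theta = (np.arange(1, na + 1) / na) * (np.pi / 2.0)  # (0, pi/2]
    phi = np.arange(nc) * (2.0 * np.pi / nc)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")  # (na, nc)
    rho = np.ones_like(tt) if radius_fn is None else radius_fn(pp, tt)
    x = cx + a * np.sin(tt) * np.cos(pp) * rho
    y = cy + b * np.sin(tt) * np.sin(pp) * rho
    z = cz - c * np.cos(tt)
    rings = np.stack([x, y, z], axis=-1)
    apex = np.array([cx, cy, cz - c])
    base_center = np.array([cx, cy, cz])
    return build_ring_shell(rings, apex, base_center)


def _rv_radius_fn(phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Crescent indentation toward the LV plus the RVOT bulge near the base."""
    septal = _RV_SEPTAL_INDENT * np.exp(
        -0.5 * (_wrap_angle(phi - np.pi) / _RV_SEPTAL_WIDTH) ** 2
    )
    rvot = (
        _RVOT_BULGE
        * np.exp(-0.5 * (_wrap_angle(phi - _RVOT_PHI) / _RVOT_PHI_WIDTH) ** 2)
        * np.exp(-0.5 * ((theta - np.pi / 2.0) / _RVOT_THETA_WIDTH) ** 2)
    )
    return 1.0 - septal + rvot


def make_template_biventricle(
    circumferential_resolution: int = 24, axial_resolution: int = 12
) -> BiVentricleMesh:
    """Build the stylised bi-ventricular template mesh.

    LV endocardium and epicardium are nested truncated half-ellipsoids
    closed with a flat basal cap; the RV endocardium is a crescent
    wrapped around the LV side with a smooth outflow-tract bulge.  Long
    axis along +z, base at z = 0, apex at negative z; units mm.

    Parameters
    ----------
    circumferential_resolution
        Points per ring (>= 8).
    axial_resolution
        Number of rings from apex to base (>= 6).
    """
    nc, na = circumferential_resolution, axial_resolution
    if nc < 8 or na < 6:
        raise InvalidArgumentError(
            f"resolutions must be >= 8 (circumferential) and >= 6 (axial); "
            f"got {nc}, {na}"
        )
    lv_endo = _capped_half_ellipsoid(_LV_ENDO_AXES, nc, na)
    lv_epi = _capped_half_ellipsoid(_LV_EPI_AXES, nc, na)
    rv_endo = _capped_half_ellipsoid(
        _RV_AXES, nc, na, center=(_RV_CENTER_X, 0.0, 0.0), radius_fn=_rv_radius_fn
    )
    return BiVentricleMesh(lv_endo=lv_endo, lv_epi=lv_epi, rv_endo=rv_endo)


# ---------------------------------------------------------------------------
# Mode fields
# ---------------------------------------------------------------------------


class ModeBasis:
    """The five planted deformation fields of a template.

    Raw fields are geometric constructions (radial scaling, weighted
    axial shifts, shear, Gaussian bumps); the working basis is their
    Gram-Schmidt orthonormalisation in the canonical mode order, so the
    planted population covariance is exactly diagonal in this basis.
    """

    def __init__(self, template: BiVentricleMesh):
        self.template = template
        self._raw = {mid: self._geometric_field(mid) for mid in MODE_IDS}
        self.matrix = self._orthonormalise()  # (5, 3V), rows orthonormal

    # -- raw geometric constructions ------------------------------------
    def _geometric_field(self, mode_id: str) -> np.ndarray:
        t = self.template
        if mode_id not in MODE_IDS:
            raise InvalidArgumentError(f"unknown mode_id {mode_id!r}")
        all_v = np.vstack([s.vertices for _, s in t.surfaces()])
        centroid = all_v.mean(axis=0)
        rv = t.rv_endo.vertices
        apex_z = all_v[:, 2].min()

        rim_r = _RV_AXES[0] * _rv_radius_fn(
            np.array([_RVOT_PHI]), np.array([np.pi / 2])
        )[0]
        p_rvot = np.array(
            [_RV_CENTER_X + rim_r * np.cos(_RVOT_PHI), _RV_AXES[1] * np.sin(_RVOT_PHI), 0.0]
        )
        inlet_r = _RV_AXES[0] * _rv_radius_fn(
            np.array([_RV_INLET_PHI]), np.array([np.pi / 2])
        )[0]
        p_inlet = np.array(
            [
                _RV_CENTER_X + inlet_r * np.cos(_RV_INLET_PHI),
                _RV_AXES[1] * np.sin(_RV_INLET_PHI),
                0.0,
            ]
        )

        disp = {name: np.zeros_like(s.vertices) for name, s in t.surfaces()}
        if mode_id == "dilation":
            # radial scaling about the bi-ventricle centroid: template +
            # s * field scales every surface by (1 + s) exactly.
            for name, s in t.surfaces():
                disp[name] = s.vertices - centroid
        elif mode_id == "length":
            # z-axis scaling about the basal plane z = 0
            for name, s in t.surfaces():
                disp[name][:, 2] = s.vertices[:, 2]
        elif mode_id == "rvot_elong":
            # axial displacement, smooth bump centred on the RVOT rim
            w = np.exp(-np.sum((rv - p_rvot) ** 2, axis=1) / (2.0 * 18.0**2))
            disp["rv_endo"][:, 2] = w
        elif mode_id == "septal_tilt":
            # linear base-to-apex shear of the RV septal wall, toward the LV
            phi = np.arctan2(rv[:, 1], rv[:, 0] - _RV_CENTER_X)
            septal_w = np.exp(-0.5 * (_wrap_angle(phi - np.pi) / 0.7) ** 2)
            axial = 1.0 - rv[:, 2] / apex_z  # 1 at base, 0 at apex
            disp["rv_endo"][:, 0] = -septal_w * axial
        elif mode_id == "inlet_outlet_bulge":
            # outward in-plane bumps at the RV inflow and outflow
            radial = rv - np.array([_RV_CENTER_X, 0.0, 0.0])
            radial[:, 2] = 0.0
            norms = np.linalg.norm(radial, axis=1)
            rhat = np.divide(
                radial,
                norms[:, None],
                out=np.zeros_like(radial),
                where=norms[:, None] > 1e-12,
            )
            w = np.exp(
                -np.sum((rv - p_inlet) ** 2, axis=1) / (2.0 * 15.0**2)
            ) + np.exp(-np.sum((rv - p_rvot) ** 2, axis=1) / (2.0 * 15.0**2))
            disp["rv_endo"] = rhat * w[:, None]

        return np.concatenate([disp[name].ravel() for name, _ in t.surfaces()])

    def _orthonormalise(self) -> np.ndarray:
        basis: list[np.ndarray] = []
        for mid in MODE_IDS:
            v = self._raw[mid].copy()
            for u in basis:
                v -= (v @ u) * u
            n = np.linalg.norm(v)
            if n < 1e-12:
                raise ConfigurationError(
                    f"mode field {mid!r} is linearly dependent on earlier modes"
                )
            basis.append(v / n)
        return np.asarray(basis)

    def raw_field(self, mode_id: str) -> np.ndarray:
        """Pre-orthonormalisation geometric field (flattened, 3V)."""
        if mode_id not in MODE_IDS:
            raise InvalidArgumentError(f"unknown mode_id {mode_id!r}")
        return self._raw[mode_id]

    def field(self, mode_id: str) -> np.ndarray:
        """Orthonormalised unit field (flattened, 3V)."""
        if mode_id not in MODE_IDS:
            raise InvalidArgumentError(f"unknown mode_id {mode_id!r}")
        return self.matrix[MODE_IDS.index(mode_id)]


def apply_mode(
    mesh: BiVentricleMesh,
    mode_id: str,
    amplitude: float,
    basis: ModeBasis | None = None,
    raw: bool = False,
) -> BiVentricleMesh:
    """Displace ``mesh`` by ``amplitude`` along a planted mode field.

    With ``raw=True`` the pre-orthonormalisation geometric field is
    used; e.g. raw ``dilation`` with amplitude ``s`` scales every
    surface by ``1 + s`` about the bi-ventricle centroid.  ``basis``
    defaults to a basis built from ``mesh`` itself; pass an explicit
    basis (built from the template) when chaining displacements.
    """
    if mode_id not in MODE_IDS:
        raise InvalidArgumentError(f"unknown mode_id {mode_id!r}")
    if basis is None:
        basis = ModeBasis(mesh)
    field_vec = basis.raw_field(mode_id) if raw else basis.field(mode_id)
    return mesh.with_flat(mesh.flatten() + amplitude * field_vec)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalLink:
    """Stochastic link from a planted mode loading to a clinical index."""

    index_name: str
    mode_id: str
    beta: float


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic population.

    ``mode_variances`` and ``residual_noise_fraction`` are fractions of
    the total population variance ``total_variance`` (mm^2, flattened
    coordinate norm) and must sum to 1.
    """

    n_subjects: int = 27
    mode_variances: dict = field(
        default_factory=lambda: dict(DEFAULT_MODE_VARIANCES)
    )
    residual_noise_fraction: float = DEFAULT_RESIDUAL_NOISE_FRACTION
    group_label: str = "ARVC"
    seed: int = 0
    clinical_links: tuple = ()
    total_variance: float = DEFAULT_TOTAL_VARIANCE
    #: Group effect: mean loading shift per mode, in within-group SD units.
    mode_mean_offsets: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if not (0.0 <= self.residual_noise_fraction < 1.0):
            raise ConfigurationError("residual_noise_fraction must be in [0, 1)")
        unknown = set(self.mode_variances) - set(MODE_IDS)
        if unknown:
            raise ConfigurationError(f"unknown mode ids {sorted(unknown)}")
        unknown_off = set(self.mode_mean_offsets) - set(MODE_IDS)
        if unknown_off:
            raise ConfigurationError(
                f"unknown mode ids in offsets {sorted(unknown_off)}"
            )
        if any(v < 0 for v in self.mode_variances.values()):
            raise ConfigurationError("mode variances must be nonnegative")
        total = sum(self.mode_variances.values()) + self.residual_noise_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mode variances + residual must sum to 1, got {total}"
            )
        if self.total_variance <= 0:
            raise ConfigurationError("total_variance must be positive")


def control_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Default control-like cohort: 21 subjects, same planted structure."""
    kw = dict(n_subjects=21, group_label="control", seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def sample_cohort(
    spec: CohortSpec, template: BiVentricleMesh, basis: ModeBasis | None = None
) -> tuple[list[BiVentricleMesh], np.ndarray]:
    """Draw a population of bi-ventricle meshes with planted mode structure.

    Subject ``i`` is ``template + sum_k z_ik sqrt(v_k T) field_k +
    eps_i`` with ``z_ik`` independent standard normals, ``T`` the total
    variance scale and ``eps_i`` isotropic per-vertex jitter carrying
    ``residual_noise_fraction * T`` of variance spread thinly across all
    coordinates.  Returns the meshes and the true loadings ``z`` (n x 5).
    """
    spec.validate()
    if basis is None:
        basis = ModeBasis(template)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    flat0 = template.flatten()
    dim = flat0.size

    z = rng.standard_normal((n, len(MODE_IDS)))
    offsets = np.array(
        [spec.mode_mean_offsets.get(mid, 0.0) for mid in MODE_IDS]
    )
    z = z + offsets[None, :]
    amplitudes = np.array(
        [
            np.sqrt(spec.mode_variances.get(mid, 0.0) * spec.total_variance)
            for mid in MODE_IDS
        ]
    )
    X = flat0[None, :] + (z * amplitudes[None, :]) @ basis.matrix
    if spec.residual_noise_fraction > 0:
        sigma = np.sqrt(spec.residual_noise_fraction * spec.total_variance / dim)
        X = X + rng.standard_normal((n, dim)) * sigma

    meshes = [template.with_flat(X[i]) for i in range(n)]
    return meshes, z


# Clinical index schema (mirrors a standard ARVC diagnostic table):
# binary flags plus the two Task Force criteria counts.
BINARY_INDICES = (
    "cmr_major",
    "cmr_minor",
    "vt_vf",
    "icd",
    "cardiac_arrest",
    "syncope",
    "ecg_major",
    "sa_ecg",
    "fat",
    "fibrosis",
)
COUNT_INDICES = ("tfc_major", "tfc_minor")


def sample_clinical_indices(
    true_loadings: np.ndarray,
    clinical_links: list[ClinicalLink] | tuple,
    seed: int,
) -> pd.DataFrame:
    """Draw clinical indices stochastically linked to planted loadings.

    Binary index ``b_i ~ Bernoulli(logistic(beta * z_i,linked))``.
    Count indices (``tfc_major`` in 1..5, ``tfc_minor`` in 0..2) are
    monotone rounded functions of the linked loading plus Gaussian
    noise.  When both counts are present an ``arvc_diagnosis`` column
    (3 definite / 2 borderline / 1 possible) is derived from the Task
    Force category rule.
    """
    z = np.asarray(true_loadings, dtype=np.float64)
    n = z.shape[0]
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    cols: dict[str, np.ndarray] = {"subject_id": np.arange(n)}

    for link in clinical_links:
        if link.index_name in seen:
            raise InvalidArgumentError(
                f"duplicate clinical link for {link.index_name!r}"
            )
        seen.add(link.index_name)
        if link.mode_id not in MODE_IDS:
            raise InvalidArgumentError(f"unknown mode_id {link.mode_id!r}")
        zk = z[:, MODE_IDS.index(link.mode_id)]
        if link.index_name in BINARY_INDICES:
            p = 1.0 / (1.0 + np.exp(-link.beta * zk))
            cols[link.index_name] = (rng.uniform(size=n) < p).astype(np.int64)
        elif link.index_name == "tfc_major":
            latent = 3.0 + link.beta * zk + 0.5 * rng.standard_normal(n)
            cols[link.index_name] = np.clip(np.round(latent), 1, 5).astype(np.int64)
        elif link.index_name == "tfc_minor":
            latent = 1.0 + link.beta * zk + 0.5 * rng.standard_normal(n)
            cols[link.index_name] = np.clip(np.round(latent), 0, 2).astype(np.int64)
        else:
            raise InvalidArgumentError(f"unknown index name {link.index_name!r}")

    table = pd.DataFrame(cols)
    if {"tfc_major", "tfc_minor"} <= set(table.columns):
        from .clinical import tfc_category

        cat_code = {"definite": 3, "borderline": 2, "possible": 1, "none": 0}
        table["arvc_diagnosis"] = [
            cat_code[tfc_category(ma, mi)]
            for ma, mi in zip(table["tfc_major"], table["tfc_minor"])
        ]
    return table
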