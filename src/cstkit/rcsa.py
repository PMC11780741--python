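"""Residual chemical shift anisotropy (RCSA) fitting.

Under weak partial alignment a nucleus K with shielding tensor sigma_K
(ppm) experiences a shift change

    dnu_K = nu * 1e-6 * PREFACTOR * sum_ij S_ij sigma_K,sym,ij   [Hz]

where S is the traceless symmetric Saupe order matrix (5 independent
elements), nu the Larmor frequency in Hz, and PREFACTOR = 2/3 the
conventional contraction constant.  Only the symmetric tensor part
contributes: the contraction of a symmetric with an antisymmetric matrix
vanishes.  Every fitted quantity (the back-calculated values at the fitted
S, residuals, Q) is invariant to the choice of PREFACTOR — the fitted S
absorbs any rescaling.

Experimental data are internally referenced delta-delta-RCSAs: the shift
change of nucleus K between two alignment conditions minus the same
difference for a reference carbon in the analyte,

    ddRCSA_K = (delta1_K - delta2_K) - (delta1_ref - delta2_ref),

which cancels the isotropic medium shift.  The fitted S is then the
difference of the two conditions' order matrices; only that difference is
observable.  The overdetermined linear system (>= 5 referenced
observations) is solved in the least-squares sense via the SVD
pseudoinverse.  Fit quality is the Q-factor, a normalized RMSE

    Q = sqrt( sum (obs - calc)^2 / sum obs^2 ),

and experimental uncertainty (0.5 Hz by default) is propagated by Monte
Carlo refitting, reporting Q as mean +/- SD over the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import ShieldingTensor

#: Contraction constant of the shift-change equation.  All fitted
#: quantities are invariant to its value (see module docstring).
PREFACTOR = 2.0 / 3.0

#: Linear rescaling from the Saupe order matrix to the alignment tensor.
ALIGNMENT_SCALE = 2.0 / 3.0

#: Singular values below RANK_TOL * s_max are treated as zero.
RANK_TOL = 1e-10

__all__ = [
    "SaupeMatrix",
    "RCSAObservation",
    "RCSADataset",
    "FitResult",
    "MonteCarloQ",
    "ConformerEnsemble",
    "back_calculate_rcsa",
    "build_design_matrix",
    "fit_saupe",
    "fit_saupe_ensemble",
    "q_factor",
    "monte_carlo_q",
    "alignment_tensor_cosine",
    "UnderdeterminedError",
    "SingularGeometryError",
]


class UnderdeterminedError(ValueError):
    """Fewer than five usable observations."""


class SingularGeometryError(ValueError):
    """Design matrix is numerically rank deficient."""

    def __init__(self, message, null_direction=None):
        super().__init__(message)
        self.null_direction = null_direction


@dataclass(frozen=True)
class SaupeMatrix:
    """Traceless symmetric 3x3 order matrix, parameterized by 5 elements.

    The irreducible parameter vector is (S_zz, S_xx - S_yy, S_xy, S_xz,
    S_yz) with S_xx + S_yy + S_zz = 0 eliminated analytically.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, float(np.abs(m).max())):
            raise ValueError("Saupe matrix must be traceless")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_params(cls, params) -> "SaupeMatrix":
        """Build from (S_zz, S_xx - S_yy, S_xy, S_xz, S_yz)."""
        szz, d, sxy, sxz, syz = np.asarray(params, dtype=float)
        sxx = 0.5 * (d - szz)
        syy = 0.5 * (-d - szz)
        return cls(
            np.array(
                [[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]
            )
        )

    def to_params(self) -> np.ndarray:
        m = self.matrix
        return np.array(
            [m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]]
        )

    def alignment_tensor(self) -> np.ndarray:
        """The alignment-tensor view A = ALIGNMENT_SCALE * S."""
        return ALIGNMENT_SCALE * self.matrix

    @classmethod
    def zero(cls) -> "SaupeMatrix":
        return cls(np.zeros((3, 3)))


@dataclass(frozen=True)
class RCSAObservation:
    nucleus_id: str
    value: float  # ddRCSA, Hz
    error: float  # Hz

    def __post_init__(self):
        if not self.error > 0:
            raise ValueError(
                f"observation {self.nucleus_id!r}: error must be > 0, got {self.error}"
            )


@dataclass(frozen=True)
class RCSADataset:
    """Referenced ddRCSA observations plus the experiment metadata."""

    observations: tuple[RCSAObservation, ...]
    reference_nucleus: str
    larmor_frequency: float  # Hz
    alignment_note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.larmor_frequency <= 0:
            raise ValueError("Larmor frequency must be positive")

    @property
    def nucleus_ids(self) -> list[str]:
        return [o.nucleus_id for o in self.observations]

    @property
    def values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations])

    @property
    def errors(self) -> np.ndarray:
        return np.array([o.error for o in self.observations])

    def with_values(self, values) -> "RCSADataset":
        obs = tuple(
            RCSAObservation(o.nucleus_id, float(v), o.error)
            for o, v in zip(self.observations, values, strict=True)
        )
        return RCSADataset(
            obs, self.reference_nucleus, self.larmor_frequency, self.alignment_note
        )


@dataclass(frozen=True)
class FitResult:
    saupe: SaupeMatrix
    back_calculated: np.ndarray  # Hz, per observation
    residuals: np.ndarray  # observed - calculated, Hz
    q_factor: float
    condition_number: float
    n_used: int
    nucleus_ids: tuple[str, ...] = ()
    q_mean: float | None = None
    q_sd: float | None = None


@dataclass(frozen=True)
class MonteCarloQ:
    q_mean: float
    q_sd: float
    samples: np.ndarray
    n_failed: int = 0


@dataclass(frozen=True)
class ConformerEnsemble:
    """Weighted conformers sharing nucleus identities (one Saupe matrix)."""

    conformers: tuple[tuple[str, dict, float], ...]  # (label, {nucleus: tensor}, weight)

    def __post_init__(self):
        confs = tuple(self.conformers)
        if not confs:
            raise ValueError("ensemble must contain at least one conformer")
        weights = np.array([w for _, _, w in confs], dtype=float)
        if np.any(weights < 0):
            raise ValueError("conformer weights must be >= 0")
        if not np.isclose(weights.sum(), 1.0, atol=1e-8):
            raise ValueError(f"conformer weights must sum to 1, got {weights.sum()}")
        keys = set(confs[0][1])
        for label, tensors, _ in confs[1:]:
            if set(tensors) != keys:
                raise KeyError(
                    f"conformer {label!r} nucleus set differs from the first conformer"
                )
        object.__setattr__(self, "conformers", confs)

    @classmethod
    def single(cls, tensors: dict) -> "ConformerEnsemble":
        return cls(((("conf1"), dict(tensors), 1.0),))

    @property
    def nucleus_ids(self) -> set[str]:
        return set(self.conformers[0][1])


def _tensor_map(tensors) -> dict[str, ShieldingTensor]:
    if isinstance(tensors, dict):
        return tensors
    return {t.nucleus_id: t for t in tensors}


def back_calculate_rcsa(
    saupe: SaupeMatrix,
    tensor: ShieldingTensor,
    larmor_frequency: float,
    prefactor: float = PREFACTOR,
) -> float:
    """Shift change (Hz) of one nucleus: the Frobenius contraction of S with
    the symmetric tensor part, scaled by nu*1e-6*prefactor (sigma in ppm)."""
    sym = tensor.symmetric_part()
    return float(
        larmor_frequency * 1e-6 * prefactor * np.sum(saupe.matrix * sym)
    )


def _design_row(sym_diff: np.ndarray) -> np.ndarray:
    """Coefficients of sum_ij S_ij M_ij in the 5-parameter Saupe basis."""
    m = sym_diff
    return np.array(
        [
            m[2, 2] - 0.5 * (m[0, 0] + m[1, 1]),
            0.5 * (m[0, 0] - m[1, 1]),
            2.0 * m[0, 1],
            2.0 * m[0, 2],
            2.0 * m[1, 2],
        ]
    )


def build_design_matrix(
    tensors,
    reference_nucleus: str,
    larmor_frequency: float,
    nucleus_ids: list[str],
    prefactor: float = PREFACTOR,
) -> np.ndarray:
    """n x 5 linear map from Saupe parameters to referenced ddRCSAs (Hz).

    Row k is built from sigma_k,sym - sigma_ref,sym, so by construction
    design @ params(S) == back_calculate(S, sigma_k) - back_calculate(S,
    sigma_ref) for every k, and isotropic shifts of any tensor are
    invisible (c*I is trace-orthogonal to the traceless S).
    """
    tmap = _tensor_map(tensors)
    if reference_nucleus not in tmap:
        raise KeyError(f"reference nucleus {reference_nucleus!r} not in tensor set")
    missing = [n for n in nucleus_ids if n not in tmap]
    if missing:
        raise KeyError(f"nuclei missing from tensor set: {missing}")
    ref_sym = tmap[reference_nucleus].symmetric_part()
    scale = larmor_frequency * 1e-6 * prefactor
    return np.vstack(
        [
            scale * _design_row(tmap[n].symmetric_part() - ref_sym)
            for n in nucleus_ids
        ]
    )


def q_factor(observed, calculated) -> float:
    """Normalized RMSE: sqrt(sum (obs-calc)^2 / sum obs^2)."""
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape:
        raise ValueError("observed and calculated lengths differ")
    denom = float(np.sum(obs**2))
    if denom == 0.0:
        raise ZeroDivisionError("Q-factor undefined: observed vector is all zero")
    return float(np.sqrt(np.sum((obs - calc) ** 2) / denom))


def _solve(design: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares via SVD pseudoinverse with explicit rank diagnostics."""
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    if s[0] == 0.0:
        raise SingularGeometryError("design matrix is identically zero")
    mask = s > RANK_TOL * s[0]
    if not mask.all():
        null_dir = vt[int(np.argmin(mask)), :]
        raise SingularGeometryError(
            "design matrix is rank deficient "
            f"(rank {int(mask.sum())} < 5); null-space direction in the "
            f"(S_zz, S_xx-S_yy, S_xy, S_xz, S_yz) basis: {np.round(null_dir, 6).tolist()}",
            null_direction=null_dir,
        )
    cond = float(s[0] / s[-1])
    params = vt.T @ ((u.T @ values) / s)
    return params, cond


def _ensemble_design(
    ensemble: ConformerEnsemble,
    reference_nucleus: str,
    larmor_frequency: float,
    nucleus_ids: list[str],
    prefactor: float,
) -> np.ndarray:
    design = np.zeros((len(nucleus_ids), 5))
    for _, tensors, weight in ensemble.conformers:
        design += weight * build_design_matrix(
            tensors, reference_nucleus, larmor_frequency, nucleus_ids, prefactor
        )
    return design


def fit_saupe_ensemble(
    dataset: RCSADataset,
    ensemble: ConformerEnsemble,
    prefactor: float = PREFACTOR,
) -> FitResult:
    """Fit one shared Saupe matrix under the single-alignment-tensor
    approximation: the design matrix is the population-weighted average over
    conformers.  A single-conformer ensemble reduces exactly to fit_saupe."""
    if dataset.reference_nucleus not in ensemble.nucleus_ids:
        raise KeyError(
            f"reference nucleus {dataset.reference_nucleus!r} not in tensor set"
        )
    obs_ids = dataset.nucleus_ids
    n = len(obs_ids)
    if n < 5:
        raise UnderdeterminedError(
            f"need >= 5 referenced observations for a determinate fit, got {n}"
        )
    design = _ensemble_design(
        ensemble, dataset.reference_nucleus, dataset.larmor_frequency, obs_ids, prefactor
    )
    values = dataset.values
    params, cond = _solve(design, values)
    calc = design @ params
    return FitResult(
        saupe=SaupeMatrix.from_params(params),
        back_calculated=calc,
        residuals=values - calc,
        q_factor=q_factor(values, calc),
        condition_number=cond,
        n_used=n,
        nucleus_ids=tuple(obs_ids),
    )


def fit_saupe(
    dataset: RCSADataset,
    tensors,
    prefactor: float = PREFACTOR,
) -> FitResult:
    """Least-squares Saupe matrix from referenced ddRCSA observations."""
    return fit_saupe_ensemble(
        dataset, ConformerEnsemble.single(_tensor_map(tensors)), prefactor
    )


def monte_carlo_q(
    dataset: RCSADataset,
    tensors_or_ensemble,
    n_samples: int = 1000,
    noise_sd: float = 0.5,
    seed: int | None = 12345,
    prefactor: float = PREFACTOR,
) -> MonteCarloQ:
    """Monte-Carlo Q distribution: refit on datasets with i.i.d. Gaussian
    noise (sd = noise_sd, Hz) added to every observation.

    Per-sample fit failures are counted in ``n_failed``, never silently
    dropped from the report.  Reproducible under a fixed seed.
    """
    if isinstance(tensors_or_ensemble, ConformerEnsemble):
        ensemble = tensors_or_ensemble
    else:
        ensemble = ConformerEnsemble.single(_tensor_map(tensors_or_ensemble))
    base = fit_saupe_ensemble(dataset, ensemble, prefactor)  # validates up front
    rng = np.random.default_rng(seed)
    values = dataset.values
    qs = []
    n_failed = 0
    for _ in range(n_samples):
        noisy = values + rng.normal(0.0, noise_sd, size=values.shape)
        try:
            qs.append(
                fit_saupe_ensemble(dataset.with_values(noisy), ensemble, prefactor).q_factor
            )
        except (SingularGeometryError, UnderdeterminedError, ZeroDivisionError):
            n_failed += 1
    samples = np.array(qs)
    if samples.size == 0:
        raise SingularGeometryError("all Monte-Carlo refits failed")
    _ = base
    return MonteCarloQ(
        q_mean=float(np.mean(samples)),
        q_sd=float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0,
        samples=samples,
        n_failed=n_failed,
    )


def alignment_tensor_cosine(a: SaupeMatrix, b: SaupeMatrix) -> float:
    """Frobenius cosine between two order matrices, in [-1, 1].

    Identical to the normalized inner product of the two matrices viewed as
    vectors in the 5-dimensional space of traceless symmetric tensors.
    """
    am, bm = a.matrix, b.matrix
    na, nb = np.linalg.norm(am), np.linalg.norm(bm)
    if na == 0.0 or nb == 0.0:
        raise ZeroDivisionError("cosine similarity undefined for a zero tensor")
    return float(np.clip(np.sum(am * bm) / (na * nb), -1.0, 1.0))
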