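"""Synthetic tensors, order matrices and RCSA observations.

Generators with the statistical structure the analysis assumes, so every
stage is testable without external data:

* reference tensors — symmetric-dominant 3x3 tensors built as
  R diag(lambda) R^t + small antisymmetric part, with R Haar-uniform and
  the diagonal parameterized by isotropic value, maryland anisotropy and
  asymmetry (emulating the diversity of a 13C benchmark set);
* method-like perturbations — independent eigenvalue noise, optional
  systematic anisotropy bias, and small-angle eigenframe rotations
  (emulating how approximate electronic-structure methods deviate from a
  high-level reference: eigenvalue errors dominate, frames are well
  reproduced);
* RCSA observations — a traceless symmetric Saupe matrix of weak-alignment
  magnitude, noiseless shift changes via the contraction formula, a common
  isotropic medium shift applied *before* internal referencing (so it
  cancels exactly), then i.i.d. Gaussian noise of stated sd (0.5 Hz by
  default, the conventional estimate of experimental ddRCSA error).

Every generator is a pure function of its seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group

from .rcsa import RCSADataset, RCSAObservation, SaupeMatrix, back_calculate_rcsa
from .tensor import ShieldingTensor, principal_components

#: 13C Larmor frequency (Hz) at a 14.1 T field (600 MHz proton).
DEFAULT_LARMOR_HZ = 150.9e6

__all__ = [
    "TensorGeneratorSpec",
    "PerturbationSpec",
    "ObservationSpec",
    "generate_reference_tensors",
    "perturb_tensors",
    "random_saupe",
    "generate_rcsa_observations",
    "DEFAULT_LARMOR_HZ",
]


@dataclass(frozen=True)
class TensorGeneratorSpec:
    n_nuclei: int = 10
    iso_range: tuple[float, float] = (20.0, 180.0)  # ppm, 13C-like
    anisotropy_range: tuple[float, float] = (30.0, 180.0)  # ppm, maryland
    asymmetry_range: tuple[float, float] = (0.0, 1.0)
    antisymmetric_scale: float = 1.0  # ppm
    include_near_degenerate: int = 0  # extra nuclei with eigenvalue gap < 3 ppm
    molecule_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        for name in ("iso_range", "anisotropy_range", "asymmetry_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well-ordered: ({lo}, {hi})")


@dataclass(frozen=True)
class PerturbationSpec:
    eigenvalue_noise_sd: float = 5.0  # ppm
    rotation_angle_sd: float = 2.0  # degrees
    systematic_anisotropy_bias: float = 0.0  # ppm, added to maryland anisotropy

    def __post_init__(self):
        if self.eigenvalue_noise_sd < 0 or self.rotation_angle_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class ObservationSpec:
    saupe_magnitude: float = 1e-3  # Frobenius norm of S, weak alignment
    noise_sd: float = 0.5  # Hz
    medium_shift: float = 0.0  # Hz, common isotropic offset before referencing
    larmor_frequency: float = DEFAULT_LARMOR_HZ  # Hz
    reference_nucleus: str = "C1"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _diag_from_shape(iso: float, aniso: float, eta: float) -> np.ndarray:
    """Maryland-ordered eigenvalues from (iso, anisotropy, asymmetry).

    lambda_3 = iso + (2/3) aniso, lambda_{1,2} = iso - (1/3) aniso (1 +/- eta);
    trace = 3 iso and sigma_33 - (sigma_11 + sigma_22)/2 = aniso exactly.
    """
    return np.array(
        [
            iso - aniso * (1.0 + eta) / 3.0,
            iso - aniso * (1.0 - eta) / 3.0,
            iso + 2.0 * aniso / 3.0,
        ]
    )


def _random_antisymmetric(rng: np.random.Generator, scale: float) -> np.ndarray:
    a = rng.normal(0.0, scale, size=3) if scale > 0 else np.zeros(3)
    return np.array(
        [[0.0, a[0], a[1]], [-a[0], 0.0, a[2]], [-a[1], -a[2], 0.0]]
    )


def generate_reference_tensors(spec: TensorGeneratorSpec) -> list[ShieldingTensor]:
    """Random reference tensor set, reproducible under the spec's seed.

    With ``include_near_degenerate > 0``, that many extra nuclei are
    appended whose two lowest eigenvalues differ by < 3 ppm, to exercise the
    degeneracy-exclusion rule downstream.
    """
    rng = np.random.default_rng(spec.seed)
    tensors = []
    total = spec.n_nuclei + spec.include_near_degenerate
    for i in range(total):
        iso = rng.uniform(*spec.iso_range)
        if i < spec.n_nuclei:
            aniso = rng.uniform(*spec.anisotropy_range)
            eta = rng.uniform(*spec.asymmetry_range)
        else:
            # near-degenerate: tiny asymmetry makes the 11/22 gap < 3 ppm
            aniso = max(rng.uniform(*spec.anisotropy_range), 30.0)
            eta = rng.uniform(0.0, 2.0 / aniso)  # gap = 2*aniso*eta/3 < 4/3 ppm
        diag = _diag_from_shape(iso, aniso, eta)
        rot = special_ortho_group.rvs(3, random_state=rng)
        m = rot @ np.diag(diag) @ rot.T + _random_antisymmetric(
            rng, spec.antisymmetric_scale
        )
        tensors.append(
            ShieldingTensor(
                molecule_id=spec.molecule_id,
                nucleus_id=f"C{i + 1}",
                matrix=m,
                frame_note=f"synthetic frame seed={spec.seed}",
            )
        )
    return tensors


def _small_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    """Rotation about a uniform random axis by a folded-Gaussian angle."""
    if angle_sd_deg == 0.0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = abs(rng.normal(0.0, math.radians(angle_sd_deg)))
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def perturb_tensors(
    base: list[ShieldingTensor], spec: PerturbationSpec, seed: int = 0
) -> list[ShieldingTensor]:
    """Method-like perturbation of a reference set.

    Eigenvalues are jittered independently (sd ``eigenvalue_noise_sd``) and
    optionally shifted by a systematic anisotropy bias b applied in the
    trace-preserving direction (+2b/3 on sigma_33, -b/3 on the others, so
    the maryland anisotropy moves by exactly b while iso is unchanged);
    eigenframes are rotated by small random angles.  With all sds and bias
    zero the output equals the symmetrized base.
    """
    rng = np.random.default_rng(seed)
    out = []
    b = spec.systematic_anisotropy_bias
    bias_vec = np.array([-b / 3.0, -b / 3.0, 2.0 * b / 3.0])
    for t in base:
        pcs = principal_components(t, "maryland")
        vals = pcs.values + bias_vec
        if spec.eigenvalue_noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.eigenvalue_noise_sd, size=3)
        rot = _small_rotation(rng, spec.rotation_angle_sd)
        vecs = rot @ pcs.vectors
        m = vecs @ np.diag(vals) @ vecs.T
        out.append(
            ShieldingTensor(
                molecule_id=t.molecule_id,
                nucleus_id=t.nucleus_id,
                matrix=0.5 * (m + m.T),
                frame_note=t.frame_note,
            )
        )
    return out


def random_saupe(magnitude: float, rng: np.random.Generator) -> SaupeMatrix:
    """Random traceless symmetric order matrix with Frobenius norm ``magnitude``."""
    params = rng.normal(size=5)
    s = SaupeMatrix.from_params(params)
    norm = np.linalg.norm(s.matrix)
    return SaupeMatrix(s.matrix * (magnitude / norm))


def generate_rcsa_observations(
    tensors,
    spec: ObservationSpec,
    true_saupe: SaupeMatrix | None = None,
    seed: int = 0,
) -> tuple[RCSADataset, SaupeMatrix]:
    """Forward-model a referenced ddRCSA dataset; returns (dataset, true S).

    The common medium shift is added to every raw per-nucleus shift change
    and removed again by the internal referencing (subtracting the reference
    nucleus), exactly as in the experiment; Gaussian noise of sd
    ``spec.noise_sd`` is then added to each referenced observation.  The
    reference nucleus itself is not emitted as an observation.
    """
    tmap = tensors if isinstance(tensors, dict) else {t.nucleus_id: t for t in tensors}
    if spec.reference_nucleus not in tmap:
        raise KeyError(f"reference nucleus {spec.reference_nucleus!r} not in tensor set")
    rng = np.random.default_rng(seed)
    saupe = true_saupe if true_saupe is not None else random_saupe(spec.saupe_magnitude, rng)
    raw = {
        n: back_calculate_rcsa(saupe, t, spec.larmor_frequency) + spec.medium_shift
        for n, t in tmap.items()
    }
    ref_val = raw[spec.reference_nucleus]
    obs = []
    for n in sorted(tmap, key=lambda k: (len(k), k)):
        if n == spec.reference_nucleus:
            continue
        value = raw[n] - ref_val
        if spec.noise_sd > 0:
            value += rng.normal(0.0, spec.noise_sd)
        obs.append(RCSAObservation(n, float(value), max(spec.noise_sd, 0.5)))
    dataset = RCSADataset(
        observations=tuple(obs),
        reference_nucleus=spec.reference_nucleus,
        larmor_frequency=spec.larmor_frequency,
        alignment_note="synthetic weak alignment (difference of two conditions)",
    )
    return dataset, saupe
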