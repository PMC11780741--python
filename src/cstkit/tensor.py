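"""Chemical shielding tensor algebra.

A nuclear shielding tensor is a 3x3 real matrix (in ppm) expressed in some
Cartesian molecular frame.  It is in general *not* symmetric: only its
symmetric part contributes to observable shifts to first order, while the
antisymmetric remainder is retained for bookkeeping.  Diagonalising the
symmetric part yields the principal components (PCs) and the principal-axis
frame.  Two ordering conventions are supported:

* ``maryland`` — eigenvalues sorted ascending, sigma_11 <= sigma_22 <= sigma_33;
  the anisotropy sigma_33 - (sigma_11 + sigma_22)/2 is non-negative by
  construction.
* ``haeberlen`` — eigenvalues sorted by distance from the isotropic value,
  |sigma_ZZ - iso| >= |sigma_XX - iso| >= |sigma_YY - iso|; the anisotropy
  sigma_ZZ - (sigma_XX + sigma_YY)/2 is signed and can flip sign under tiny
  eigenvalue perturbations when two PCs of opposite sign sit nearly
  equidistant from the isotropic value.

A third, rotationally invariant anisotropy (the form printed by quantum
chemistry codes such as Turbomole) is available under the ``turbomole``
convention: sqrt(3/2 * sum_i (lambda_i - iso)^2), which is independent of
any eigenvalue ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONVENTIONS = ("haeberlen", "maryland", "turbomole")

__all__ = [
    "ShieldingTensor",
    "TensorDecomposition",
    "PrincipalComponents",
    "AnisotropyValue",
    "decompose",
    "principal_components",
    "isotropic_shielding",
    "anisotropy",
    "CONVENTIONS",
]


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"shielding tensor must be 3x3, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("shielding tensor contains non-finite entries")
    return m


@dataclass(frozen=True)
class ShieldingTensor:
    """Raw per-nucleus shielding tensor in ppm.

    ``matrix`` need not be symmetric; ``frame_note`` documents the Cartesian
    orientation the tensor is expressed in (tensors from different sources
    are only comparable when their frames match).
    """

    molecule_id: str
    nucleus_id: str
    matrix: np.ndarray
    frame_note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "matrix", _as_matrix(self.matrix))

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule_id, self.nucleus_id)

    def symmetric_part(self) -> np.ndarray:
        return 0.5 * (self.matrix + self.matrix.T)


@dataclass(frozen=True)
class TensorDecomposition:
    symmetric: np.ndarray
    antisymmetric: np.ndarray


@dataclass(frozen=True)
class PrincipalComponents:
    """Eigenvalues/eigenvectors of the symmetric tensor part under a named ordering.

    ``vectors[:, i]`` is the unit eigenvector belonging to ``values[i]``.
    For maryland ordering the index runs 0..2 over (sigma_11, sigma_22,
    sigma_33); for haeberlen it runs over (sigma_XX, sigma_YY, sigma_ZZ).
    """

    values: np.ndarray
    vectors: np.ndarray
    convention: str
    iso: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=float))
        if self.iso is None:
            object.__setattr__(self, "iso", float(np.mean(self.values)))


@dataclass(frozen=True)
class AnisotropyValue:
    value: float
    convention: str
    molecule_id: str = ""
    nucleus_id: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule_id, self.nucleus_id)


def decompose(tensor: ShieldingTensor) -> TensorDecomposition:
    """Split a tensor into symmetric and antisymmetric parts.

    symmetric = (T + T^t)/2, antisymmetric = (T - T^t)/2; the two parts
    reconstruct the input exactly.
    """
    m = tensor.matrix
    return TensorDecomposition(symmetric=0.5 * (m + m.T), antisymmetric=0.5 * (m - m.T))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude component is positive."""
    out = vectors.copy()
    for i in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, i])))
        if out[j, i] < 0:
            out[:, i] = -out[:, i]
    return out


def principal_components(
    tensor: ShieldingTensor, convention: str = "maryland"
) -> PrincipalComponents:
    """Principal components of the symmetric tensor part under a convention.

    Eigenvectors are returned with a deterministic sign (largest-magnitude
    component positive).  Haeberlen tie-break: when the X and Y deviations
    from the isotropic value are equal in magnitude, the larger eigenvalue
    is assigned to sigma_XX.
    """
    if convention not in ("haeberlen", "maryland"):
        raise ValueError(
            f"unknown ordering convention {convention!r}; expected 'haeberlen' or 'maryland'"
        )
    sym = tensor.symmetric_part()
    vals, vecs = np.linalg.eigh(sym)  # ascending
    iso = float(np.mean(vals))
    if convention == "maryland":
        order = np.arange(3)
    else:
        dev = np.abs(vals - iso)
        # sigma_ZZ = largest |deviation|; remaining two ordered |XX| >= |YY|,
        # ties broken by assigning the larger eigenvalue to sigma_XX.
        zz = int(np.argmax(dev))
        rest = [i for i in range(3) if i != zz]
        a, b = rest
        if not np.isclose(dev[a], dev[b]):
            xx, yy = (a, b) if dev[a] > dev[b] else (b, a)
        else:
            xx, yy = (a, b) if vals[a] >= vals[b] else (b, a)
        order = np.array([xx, yy, zz])
    return PrincipalComponents(
        values=vals[order],
        vectors=_fix_signs(vecs[:, order]),
        convention=convention,
        iso=iso,
    )


def isotropic_shielding(tensor: ShieldingTensor) -> float:
    """Isotropic shielding, trace/3 — invariant under frame rotation."""
    return float(np.trace(tensor.matrix) / 3.0)


def anisotropy(pcs: PrincipalComponents, convention: str | None = None) -> AnisotropyValue:
    """Shielding anisotropy under one of the three conventions.

    haeberlen: sigma_ZZ - (sigma_XX + sigma_YY)/2 (signed, requires haeberlen
    ordering); maryland: sigma_33 - (sigma_11 + sigma_22)/2 (>= 0, requires
    maryland ordering); turbomole: sqrt(3/2 * sum (lambda - iso)^2),
    ordering-independent and >= 0.
    """
    if convention is None:
        convention = pcs.convention
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown anisotropy convention {convention!r}")
    v = pcs.values
    if convention == "turbomole":
        value = float(np.sqrt(1.5 * np.sum((v - pcs.iso) ** 2)))
    elif convention == "maryland":
        if pcs.convention != "maryland":
            raise ValueError(
                "maryland anisotropy requires maryland-ordered principal components"
            )
        value = float(v[2] - 0.5 * (v[0] + v[1]))
    else:
        if pcs.convention != "haeberlen":
            raise ValueError(
                "haeberlen anisotropy requires haeberlen-ordered principal components"
            )
        value = float(v[2] - 0.5 * (v[0] + v[1]))
    return AnisotropyValue(value=value, convention=convention)


def tensor_anisotropy(
    tensor: ShieldingTensor, convention: str = "maryland"
) -> AnisotropyValue:
    """Convenience: anisotropy straight from a tensor, carrying its identity."""
    ordering = "haeberlen" if convention == "haeberlen" else "maryland"
    a = anisotropy(principal_components(tensor, ordering), convention)
    return AnisotropyValue(
        value=a.value,
        convention=convention,
        molecule_id=tensor.molecule_id,
        nucleus_id=tensor.nucleus_id,
    )
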