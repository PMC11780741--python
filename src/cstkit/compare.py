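"""Benchmarking a test tensor set against a reference tensor set.

Three complementary criteria:

* anisotropy error statistics (MSE / MAE / SD / max-AE) on paired
  per-nucleus anisotropies, errors defined as test - reference;
* the direction criterion — sign-resolved angles between corresponding
  principal-axis eigenvectors, with axes excluded when the reference
  eigenvalues are nearly degenerate (default gap threshold 3 ppm), since a
  near-degenerate PC direction is not well defined;
* the shape criterion — the angle between two tensors under the Frobenius
  inner product, either on the full unsymmetrized 3x3 matrices or on the
  3-vectors of maryland principal values (the two give nearly
  indistinguishable shape measures).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor import (
    AnisotropyValue,
    PrincipalComponents,
    ShieldingTensor,
    principal_components,
    tensor_anisotropy,
)

AXES = ("X", "Y", "Z")

__all__ = [
    "ErrorStats",
    "AxisComparison",
    "SimilarityReport",
    "MethodReport",
    "anisotropy_error_stats",
    "eigenvector_similarity",
    "tensor_shape_similarity",
    "summarize_method",
]


class KeyMismatchError(KeyError):
    """Reference and test sets do not cover the same nuclei."""

    def __init__(self, missing_in_test, missing_in_reference):
        self.missing_in_test = sorted(missing_in_test)
        self.missing_in_reference = sorted(missing_in_reference)
        super().__init__(
            "unpaired nuclei: "
            f"missing in test {self.missing_in_test}, "
            f"missing in reference {self.missing_in_reference}"
        )


@dataclass(frozen=True)
class ErrorStats:
    mse: float
    mae: float
    sd: float
    max_ae: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "sd": self.sd,
            "max_ae": self.max_ae,
            "n": self.n,
        }


@dataclass(frozen=True)
class AxisComparison:
    axis: str
    angle_deg: float | None
    excluded: bool
    reason: str = ""


@dataclass(frozen=True)
class SimilarityReport:
    """Per-nucleus direction + shape comparison."""

    molecule_id: str
    nucleus_id: str
    axes: tuple[AxisComparison, AxisComparison, AxisComparison]
    shape_angle_deg: float

    def angle(self, axis: str) -> float | None:
        for c in self.axes:
            if c.axis == axis:
                return c.angle_deg
        raise KeyError(axis)


def anisotropy_error_stats(
    reference: list[AnisotropyValue], test: list[AnisotropyValue]
) -> ErrorStats:
    """Benchmark statistics on paired anisotropies (errors = test - reference).

    SD is the sample standard deviation (n-1 denominator) of the signed
    errors.  Pairing is by (molecule_id, nucleus_id); unpaired keys raise.
    """
    ref_map = {a.key: a for a in reference}
    test_map = {a.key: a for a in test}
    if set(ref_map) != set(test_map):
        raise KeyMismatchError(
            set(ref_map) - set(test_map), set(test_map) - set(ref_map)
        )
    conv = {a.convention for a in reference} | {a.convention for a in test}
    if len(conv) > 1:
        raise ValueError(f"mixed anisotropy conventions in comparison: {sorted(conv)}")
    keys = sorted(ref_map)
    err = np.array([test_map[k].value - ref_map[k].value for k in keys])
    if err.size == 0:
        raise ValueError("empty comparison")
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return ErrorStats(
        mse=float(np.mean(err)),
        mae=float(np.mean(np.abs(err))),
        sd=sd,
        max_ae=float(np.max(np.abs(err))),
        n=int(err.size),
    )


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Sign-resolved angle in degrees, in [0, 90]."""
    c = abs(float(np.dot(u, v)))
    return math.degrees(math.acos(min(1.0, c)))


def eigenvector_similarity(
    ref_pcs: PrincipalComponents,
    test_pcs: PrincipalComponents,
    degeneracy_threshold: float = 3.0,
    best_match: bool = False,
) -> tuple[AxisComparison, AxisComparison, AxisComparison]:
    """Per-axis eigenvector angles with degeneracy exclusion.

    Axes are paired by maryland rank.  An axis is excluded when, in the
    *reference* principal values, the minimum gap between its eigenvalue and
    any other is below ``degeneracy_threshold`` (ppm).  Eigenvector signs are
    arbitrary, so the angle is computed on |u.v| and lies in [0, 90] degrees.

    ``best_match=True`` is a diagnostic mode that pairs each reference axis
    with the test axis of largest |cosine| instead of by rank.
    """
    if ref_pcs.convention != "maryland" or test_pcs.convention != "maryland":
        raise ValueError("eigenvector similarity requires maryland-ordered PCs")
    for pcs in (ref_pcs, test_pcs):
        g = pcs.vectors.T @ pcs.vectors
        if not np.allclose(g, np.eye(3), atol=1e-8):
            raise ValueError("principal-axis vectors are not orthonormal")
    vals = ref_pcs.values
    out = []
    for i, axis in enumerate(AXES):
        gap = min(abs(vals[i] - vals[j]) for j in range(3) if j != i)
        if gap < degeneracy_threshold:
            out.append(
                AxisComparison(
                    axis=axis,
                    angle_deg=None,
                    excluded=True,
                    reason=f"reference eigenvalue gap {gap:.3g} ppm < {degeneracy_threshold:g} ppm",
                )
            )
            continue
        u = ref_pcs.vectors[:, i]
        if best_match:
            angle = min(
                _angle_between(u, test_pcs.vectors[:, j]) for j in range(3)
            )
        else:
            angle = _angle_between(u, test_pcs.vectors[:, i])
        out.append(AxisComparison(axis=axis, angle_deg=angle, excluded=False))
    return tuple(out)


def tensor_shape_similarity(
    ref: ShieldingTensor, test: ShieldingTensor, mode: str = "full_unsymmetrized"
) -> float:
    """Shape angle Delta-Theta_T in degrees, in [0, 180].

    ``full_unsymmetrized``: arccos of the normalized Frobenius inner product
    of the raw 3x3 matrices.  ``pc_vector``: same formula applied to the
    3-vectors of maryland principal values.  Scale-invariant (positive
    rescaling gives 0 degrees against itself).
    """
    if mode == "full_unsymmetrized":
        a = ref.matrix.ravel()
        b = test.matrix.ravel()
    elif mode == "pc_vector":
        a = principal_components(ref, "maryland").values
        b = principal_components(test, "maryland").values
    else:
        raise ValueError(f"unknown shape mode {mode!r}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ZeroDivisionError("shape similarity undefined for a zero-norm tensor")
    c = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


@dataclass
class MethodReport:
    """Summary of one test method against the reference set."""

    method: str
    error_stats: dict[str, ErrorStats]
    similarities: list[SimilarityReport] = field(default_factory=list)

    def retained_counts(self) -> dict[str, int]:
        return {
            ax: sum(1 for s in self.similarities if not s.axes[i].excluded)
            for i, ax in enumerate(AXES)
        }

    def mean_angles(self) -> dict[str, float]:
        out = {}
        for i, ax in enumerate(AXES):
            a = [s.axes[i].angle_deg for s in self.similarities if not s.axes[i].excluded]
            out[ax] = float(np.mean(a)) if a else float("nan")
        return out

    def max_angles(self) -> dict[str, float]:
        out = {}
        for i, ax in enumerate(AXES):
            a = [s.axes[i].angle_deg for s in self.similarities if not s.axes[i].excluded]
            out[ax] = float(np.max(a)) if a else float("nan")
        return out

    def shape_angles(self) -> np.ndarray:
        return np.array([s.shape_angle_deg for s in self.similarities])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.similarities:
            for c in s.axes:
                rows.append(
                    {
                        "molecule_id": s.molecule_id,
                        "nucleus_id": s.nucleus_id,
                        "metric": f"eigenvector_angle_{c.axis}",
                        "value": c.angle_deg,
                        "excluded": c.excluded,
                        "reason": c.reason,
                    }
                )
            rows.append(
                {
                    "molecule_id": s.molecule_id,
                    "nucleus_id": s.nucleus_id,
                    "metric": "shape_angle",
                    "value": s.shape_angle_deg,
                    "excluded": False,
                    "reason": "",
                }
            )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "method": self.method,
            "error_stats": {k: v.as_dict() for k, v in self.error_stats.items()},
            "retained_counts": self.retained_counts(),
            "mean_eigenvector_angles_deg": self.mean_angles(),
            "max_eigenvector_angles_deg": self.max_angles(),
            "mean_shape_angle_deg": float(np.mean(self.shape_angles()))
            if self.similarities
            else float("nan"),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2)


def summarize_method(
    reference: list[ShieldingTensor],
    test: list[ShieldingTensor],
    method: str = "test",
    degeneracy_threshold: float = 3.0,
    conventions: tuple[str, ...] = ("maryland", "haeberlen", "turbomole"),
    shape_mode: str = "full_unsymmetrized",
    check_frames: bool = True,
) -> MethodReport:
    """Full per-method benchmark report against a reference tensor set.

    Refuses tensor pairs whose frame notes differ (a frame mismatch silently
    invalidates every orientation comparison) unless ``check_frames=False``.
    """
    ref_map = {t.key: t for t in reference}
    test_map = {t.key: t for t in test}
    if set(ref_map) != set(test_map):
        raise KeyMismatchError(
            set(ref_map) - set(test_map), set(test_map) - set(ref_map)
        )
    keys = sorted(ref_map)
    if check_frames:
        bad = [
            k for k in keys if ref_map[k].frame_note != test_map[k].frame_note
        ]
        if bad:
            raise ValueError(
                f"frame-note mismatch for {bad[:5]}{'...' if len(bad) > 5 else ''}; "
                "tensors in different orientations are not comparable "
                "(pass check_frames=False to override)"
            )
    stats = {
        conv: anisotropy_error_stats(
            [tensor_anisotropy(ref_map[k], conv) for k in keys],
            [tensor_anisotropy(test_map[k], conv) for k in keys],
        )
        for conv in conventions
    }
    sims = []
    for k in keys:
        r, t = ref_map[k], test_map[k]
        axes = eigenvector_similarity(
            principal_components(r, "maryland"),
            principal_components(t, "maryland"),
            degeneracy_threshold=degeneracy_threshold,
        )
        sims.append(
            SimilarityReport(
                molecule_id=r.molecule_id,
                nucleus_id=r.nucleus_id,
                axes=axes,
                shape_angle_deg=tensor_shape_similarity(r, t, shape_mode),
            )
        )
    return MethodReport(method=method, error_stats=stats, similarities=sims)
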