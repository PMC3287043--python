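"""B-spline kernel: knot vectors, Cox-de Boor bases, curves, surfaces, volumes.

Everything downstream (ventricular geometry, isogeometric strain) is built on
the primitives in this module.  Bases follow the Cox-de Boor recursion with
the 0/0 := 0 convention; parameter spans are half-open, closed at the global
right endpoint so the full domain boundary is evaluable.  Indices are 0-based.

Two knot-vector forms are supported:

* ``open`` (clamped): first and last knots repeated ``degree + 1`` times, so
  the curve interpolates the end control points.
* ``periodic``: uniform knots with ``degree`` wrapped padding knots on each
  side; the associated control arrays repeat their first ``degree`` entries so
  evaluation closes seamlessly.  Used for the circumferential direction of
  ventricular models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "KnotVector",
    "ControlGrid3D",
    "SurfaceModel",
    "SolidModel",
    "basis_value",
    "basis_derivative",
    "basis_row",
    "basis_derivative_row",
    "basis_matrix",
    "make_knot_vector",
    "evaluate_curve",
    "evaluate_surface",
    "evaluate_volume",
]


class ValidationError(ValueError):
    """Raised when a model or argument violates a structural invariant."""


class DomainError(ValueError):
    """Raised when a parameter lies outside the evaluable span."""


# ---------------------------------------------------------------------------
# Knot vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnotVector:
    """Nondecreasing knot sequence ``t_0 <= ... <= t_{n+k+1}`` with degree k.

    ``nbasis`` (= n+1) basis functions are defined; the evaluable domain is
    ``[t_k, t_{n+1}]``.  For the periodic form, parameters wrap onto the
    domain modulo its length.
    """

    values: np.ndarray
    degree: int
    form: Literal["open", "periodic"] = "open"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.degree < 0:
            raise ValidationError("degree must be nonnegative")
        if vals.ndim != 1 or vals.size < 2 * (self.degree + 1):
            raise ValidationError(
                f"knot vector needs at least {2 * (self.degree + 1)} values, "
                f"got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("knot values must be finite")
        if np.any(np.diff(vals) < 0):
            raise ValidationError("knot values must be nondecreasing")
        if self.form == "open":
            k = self.degree
            if not (np.allclose(vals[: k + 1], vals[0])
                    and np.allclose(vals[-k - 1:], vals[-1])):
                raise ValidationError(
                    "open-clamped form must repeat end knots degree+1 times"
                )
        elif self.form != "periodic":
            raise ValidationError(f"unknown knot form {self.form!r}")

    # -- structure ---------------------------------------------------------

    @property
    def nbasis(self) -> int:
        return self.values.size - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.values[self.degree]), float(self.values[self.nbasis])

    def wrap(self, t: float) -> float:
        """Map a parameter into the evaluable domain (modulo, if periodic)."""
        lo, hi = self.domain
        if self.form == "periodic":
            return lo + (t - lo) % (hi - lo)
        if t < lo - 1e-12 or t > hi + 1e-12:
            raise DomainError(f"parameter {t} outside evaluation span [{lo}, {hi}]")
        return min(max(t, lo), hi)

    def find_span(self, t: float) -> int:
        """Index ``s`` with ``t_s <= t < t_{s+1}`` (right-closed at the end)."""
        lo, hi = self.domain
        vals = self.values
        if t >= hi:  # right-end convention: last positive-length span
            s = self.nbasis - 1
            while s > self.degree and vals[s] == vals[s + 1]:
                s -= 1
            return s
        s = int(np.searchsorted(vals, t, side="right")) - 1
        return min(max(s, self.degree), self.nbasis - 1)

    # -- constructors ------------------------------------------------------

    @staticmethod
    def clamped_uniform(nbasis: int, degree: int) -> "KnotVector":
        """Open-clamped knots on [0,1] with equally spaced interior knots."""
        if nbasis < degree + 1:
            raise ValidationError("need at least degree+1 basis functions")
        n_int = nbasis - degree - 1
        interior = np.linspace(0.0, 1.0, n_int + 2)[1:-1]
        vals = np.concatenate(
            [np.zeros(degree + 1), interior, np.ones(degree + 1)]
        )
        return KnotVector(vals, degree, "open")

    @staticmethod
    def periodic_uniform(n_unique: int, degree: int) -> "KnotVector":
        """Uniform periodic knots on [0,1] for ``n_unique`` distinct control
        columns (``n_unique + degree`` basis functions after wrapping)."""
        if n_unique < degree + 1:
            raise ValidationError("periodic direction needs > degree control columns")
        i = np.arange(n_unique + 2 * degree + 1)
        vals = (i - degree) / n_unique
        return KnotVector(vals, degree, "periodic")


# ---------------------------------------------------------------------------
# Basis evaluation
# ---------------------------------------------------------------------------


def basis_value(knots: KnotVector, i: int, t: float) -> float:
    """Value of the B-spline basis ``N_{i,k}(t)`` by the Cox-de Boor recursion.

    Zero-length spans contribute 0 (the 0/0 := 0 convention); the half-open
    degree-0 indicator is closed at the global right endpoint so the last
    basis of a clamped vector evaluates to 1 there.
    """
    if not 0 <= i < knots.nbasis:
        raise ValidationError(f"basis index {i} out of range [0, {knots.nbasis - 1}]")
    t = knots.wrap(t)
    row = basis_row(knots, t)
    return float(row[i])


def basis_row(knots: KnotVector, t: float) -> np.ndarray:
    """All ``nbasis`` basis values at ``t`` (dense vector, mostly zeros).

    Uses the span-local triangular scheme: only the ``degree + 1`` bases
    supported on the containing span are nonzero.
    """
    t = knots.wrap(t)
    k = knots.degree
    vals = knots.values
    s = knots.find_span(t)
    # triangular table of the k+1 nonvanishing bases N_{s-k..s, k}
    N = np.zeros(k + 1)
    N[0] = 1.0
    left = np.empty(k + 1)
    right = np.empty(k + 1)
    for j in range(1, k + 1):
        left[j] = t - vals[s + 1 - j]
        right[j] = vals[s + j] - t
        saved = 0.0
        for r in range(j):
            denom = right[r + 1] + left[j - r]
            temp = N[r] / denom if denom != 0.0 else 0.0
            N[r] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        N[j] = saved
    out = np.zeros(knots.nbasis)
    out[s - k: s + 1] = N
    return out


def basis_derivative(knots: KnotVector, i: int, t: float) -> float:
    """First derivative ``dN_{i,k}/dt`` via the two-term lower-degree formula.

    ``dN_{i,k}/dt = k [ N_{i,k-1}/(t_{i+k}-t_i) - N_{i+1,k-1}/(t_{i+k+1}-t_{i+1}) ]``
    with vanishing denominators contributing 0.
    """
    if not 0 <= i < knots.nbasis:
        raise ValidationError(f"basis index {i} out of range [0, {knots.nbasis - 1}]")
    if knots.degree < 1:
        return 0.0
    return float(basis_derivative_row(knots, t)[i])


def basis_derivative_row(knots: KnotVector, t: float) -> np.ndarray:
    """All ``nbasis`` first-derivative values at ``t``."""
    k = knots.degree
    if k < 1:
        return np.zeros(knots.nbasis)
    t = knots.wrap(t)
    vals = knots.values
    # degree k-1 bases indexed on the SAME knot sequence (nbasis+1 of them)
    low = _basis_row_given_degree(vals, k - 1, t, knots)
    out = np.zeros(knots.nbasis)
    for i in range(knots.nbasis):
        d1 = vals[i + k] - vals[i]
        d2 = vals[i + k + 1] - vals[i + 1]
        a = low[i] / d1 if d1 != 0.0 else 0.0
        b = low[i + 1] / d2 if d2 != 0.0 else 0.0
        out[i] = k * (a - b)
    return out


def _basis_row_given_degree(vals: np.ndarray, deg: int, t: float,
                            parent: KnotVector) -> np.ndarray:
    """Row of degree-``deg`` bases over the full knot sequence ``vals``.

    Helper for the derivative formula, which needs degree k-1 bases indexed on
    the parent's knot sequence (nbasis_parent + 1 of them).
    """
    nb = vals.size - deg - 1
    lo, hi = parent.domain
    s = parent.find_span(t)
    # triangular scheme anchored at the same span (valid: span contains t)
    N = np.zeros(deg + 1)
    N[0] = 1.0
    for j in range(1, deg + 1):
        saved = 0.0
        for r in range(j):
            denom = (vals[s + r + 1] - t) + (t - vals[s + 1 - j + r])
            temp = N[r] / denom if denom != 0.0 else 0.0
            N[r] = saved + (vals[s + r + 1] - t) * temp
            saved = (t - vals[s + 1 - j + r]) * temp
        N[j] = saved
    out = np.zeros(nb)
    out[s - deg: s + 1] = N
    return out


def basis_matrix(knots: KnotVector, ts: Sequence[float],
                 fold: int | None = None) -> np.ndarray:
    """Design matrix ``A[p, i] = N_{i,k}(t_p)``.

    With ``fold=N`` (periodic fitting) the ``nbasis = N + degree`` columns are
    folded modulo N, so column q accumulates every basis whose wrapped control
    index is q.  The folded matrix multiplies the N unique control columns.
    """
    A = np.stack([basis_row(knots, float(t)) for t in ts])
    if fold is None:
        return A
    out = np.zeros((A.shape[0], fold))
    for i in range(A.shape[1]):
        out[:, i % fold] += A[:, i]
    return out


# ---------------------------------------------------------------------------
# Knot placement
# ---------------------------------------------------------------------------


def make_knot_vector(params: Sequence[float], degree: int,
                     method: str = "riesenfeld") -> KnotVector:
    """Open-clamped knot vector on [0,1] from an ordered parameter list.

    ``riesenfeld``: interior knots by averaging ``degree`` consecutive
    parameters (knot averaging).  ``hartley_judd``: interior knot spacing
    proportional to sliding-window sums of the parameter chord lengths.
    ``uniform``: equally spaced interior knots (synthetic fixtures).
    """
    p = np.asarray(params, dtype=float)
    if p.ndim != 1 or p.size < degree + 1:
        raise ValidationError(
            f"need at least degree+1={degree + 1} parameters, got {p.size}"
        )
    if np.any(np.diff(p) <= 0):
        raise ValidationError("parameters must be strictly increasing")
    p = (p - p[0]) / (p[-1] - p[0])
    n = p.size - 1  # basis count - 1
    n_int = n - degree  # number of interior knots
    if n_int <= 0:
        interior = np.empty(0)
    elif method == "riesenfeld":
        interior = np.array(
            [p[j: j + degree].mean() for j in range(1, n_int + 1)]
        )
    elif method == "hartley_judd":
        chords = np.diff(p)
        windows = np.array(
            [chords[j: j + degree].sum() for j in range(0, n - degree + 1)]
        )
        cum = np.cumsum(windows) / windows.sum()
        interior = cum[:-1]
    elif method == "uniform":
        interior = np.linspace(0.0, 1.0, n_int + 2)[1:-1]
    else:
        raise ValidationError(f"unknown knot method {method!r}")
    vals = np.concatenate(
        [np.zeros(degree + 1), interior, np.ones(degree + 1)]
    )
    return KnotVector(vals, degree, "open")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class ControlGrid3D:
    """Rank-3 lattice of 3-D control points, shape (nc, nl, nr, 3), in mm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 4 or pts.shape[-1] != 3:
            raise ValidationError(
                f"control grid must have shape (nc, nl, nr, 3), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("control grid contains non-finite coordinates")
        self.points = pts

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.points.shape[:3]


def _check_dims(knots: KnotVector, n: int, axis: str) -> None:
    if knots.nbasis != n:
        raise ValidationError(
            f"{axis}: knot vector defines {knots.nbasis} bases but the control "
            f"array has {n} entries"
        )
    if n < knots.degree + 1:
        raise ValidationError(f"{axis}: need at least degree+1 control points")


@dataclass
class SurfaceModel:
    """Tensor-product B-spline surface S(t, w) = sum p_ij N_i(t) N_j(w).

    ``net`` has shape (n+1, m+1, 3).  The first (t) direction may be periodic,
    in which case the net's trailing ``degree`` rows duplicate its first ones.
    """

    net: np.ndarray
    knots_t: KnotVector
    knots_w: KnotVector

    def __post_init__(self) -> None:
        self.net = np.asarray(self.net, dtype=float)
        if self.net.ndim != 3 or self.net.shape[-1] != 3:
            raise ValidationError("surface net must have shape (n+1, m+1, 3)")
        _check_dims(self.knots_t, self.net.shape[0], "t direction")
        _check_dims(self.knots_w, self.net.shape[1], "w direction")
        if self.knots_w.form == "periodic":
            raise ValidationError("w (long-axis) direction must be open-clamped")

    @property
    def degrees(self) -> tuple[int, int]:
        return self.knots_t.degree, self.knots_w.degree

    def evaluate(self, t: float, w: float) -> np.ndarray:
        return evaluate_surface(self, t, w)

    def to_dict(self) -> dict:
        return {
            "type": "surface",
            "coordinate_system": "cartesian",
            "degrees": list(self.degrees),
            "knots_t": {"values": self.knots_t.values.tolist(),
                        "form": self.knots_t.form},
            "knots_w": {"values": self.knots_w.values.tolist(),
                        "form": self.knots_w.form},
            "net_shape": list(self.net.shape),
            "net": self.net.ravel().tolist(),  # row-major
        }

    @staticmethod
    def from_dict(d: dict) -> "SurfaceModel":
        k1, k2 = d["degrees"]
        kt = KnotVector(np.asarray(d["knots_t"]["values"]), k1, d["knots_t"]["form"])
        kw = KnotVector(np.asarray(d["knots_w"]["values"]), k2, d["knots_w"]["form"])
        net = np.asarray(d["net"], dtype=float).reshape(d["net_shape"])
        return SurfaceModel(net, kt, kw)


@dataclass
class SolidModel:
    """Trivariate B-spline solid V(t, w, u) over a hexahedral control grid.

    Directions: t = circumferential (may be periodic), w = long-axis,
    u = radial (inner wall at u=0, outer wall at u=1).
    """

    grid: ControlGrid3D
    knots_c: KnotVector
    knots_l: KnotVector
    knots_r: KnotVector
    coordinate_system: str = "cartesian"

    def __post_init__(self) -> None:
        if isinstance(self.grid, np.ndarray):
            self.grid = ControlGrid3D(self.grid)
        nc, nl, nr = self.grid.shape
        _check_dims(self.knots_c, nc, "circumferential")
        _check_dims(self.knots_l, nl, "long-axis")
        _check_dims(self.knots_r, nr, "radial")
        for name, kv in (("long-axis", self.knots_l), ("radial", self.knots_r)):
            if kv.form == "periodic":
                raise ValidationError(f"{name} direction must be open-clamped")

    @property
    def degrees(self) -> tuple[int, int, int]:
        return self.knots_c.degree, self.knots_l.degree, self.knots_r.degree

    def evaluate(self, t: float, w: float, u: float) -> np.ndarray:
        return evaluate_volume(self, t, w, u)

    def to_dict(self) -> dict:
        return {
            "type": "solid",
            "coordinate_system": self.coordinate_system,
            "degrees": list(self.degrees),
            "knots_c": {"values": self.knots_c.values.tolist(),
                        "form": self.knots_c.form},
            "knots_l": {"values": self.knots_l.values.tolist(),
                        "form": self.knots_l.form},
            "knots_r": {"values": self.knots_r.values.tolist(),
                        "form": self.knots_r.form},
            "grid_shape": list(self.grid.points.shape),
            "grid": self.grid.points.ravel().tolist(),  # row-major
        }

    @staticmethod
    def from_dict(d: dict) -> "SolidModel":
        k1, k2, k3 = d["degrees"]
        kc = KnotVector(np.asarray(d["knots_c"]["values"]), k1, d["knots_c"]["form"])
        kl = KnotVector(np.asarray(d["knots_l"]["values"]), k2, d["knots_l"]["form"])
        kr = KnotVector(np.asarray(d["knots_r"]["values"]), k3, d["knots_r"]["form"])
        grid = np.asarray(d["grid"], dtype=float).reshape(d["grid_shape"])
        return SolidModel(ControlGrid3D(grid), kc, kl, kr,
                          d.get("coordinate_system", "cartesian"))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_curve(control: np.ndarray, knots: KnotVector, t: float) -> np.ndarray:
    """Point on the curve C(t) = sum_i p_i N_{i,k}(t)."""
    control = np.asarray(control, dtype=float)
    _check_dims(knots, control.shape[0], "curve")
    return basis_row(knots, t) @ control


def evaluate_surface(surface: SurfaceModel, t: float, w: float) -> np.ndarray:
    """Point on the tensor-product surface S(t, w)."""
    bt = basis_row(surface.knots_t, t)
    bw = basis_row(surface.knots_w, w)
    return np.einsum("i,j,ijd->d", bt, bw, surface.net)


def evaluate_volume(solid: SolidModel, t: float, w: float, u: float,
                    grid: np.ndarray | None = None) -> np.ndarray:
    """Point of the trivariate solid V(t, w, u); ``grid`` overrides the
    control values (used to evaluate displacement grids with the same basis)."""
    g = solid.grid.points if grid is None else np.asarray(grid, dtype=float)
    bc = basis_row(solid.knots_c, t)
    bl = basis_row(solid.knots_l, w)
    br = basis_row(solid.knots_r, u)
    return np.einsum("i,j,k,ijkd->d", bc, bl, br, g)
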