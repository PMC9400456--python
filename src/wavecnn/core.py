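"""Forward dynamics of the cellular neural network (CNN, Chua–Yang style).

A CNN is a grid of locally coupled dynamical cells.  Cell ``ij`` carries a
state :math:`x_{ij}(t)` evolving under

.. math::

    \\dot x_{ij} = -x_{ij} + \\sum_{mn} a_{mn}\\, y_{i+m-2,j+n-2}
                 + \\sum_{mn} b_{mn}\\, u_{i+m-2,j+n-2} + I

where the sums run over the 3x3 neighborhood window (``m, n`` in {1,2,3},
center at ``m=n=2``), ``u`` is the input grid and the cell output is the
saturating piecewise-linear function

.. math::

    y_{ij} = \\tfrac12\\big(|x_{ij}+1| - |x_{ij}-1|\\big) \\in [-1, 1].

The shared 3x3 matrices ``A`` (feedback, couples neighbor *outputs*),
``B`` (control, couples neighbor *inputs*) and the scalar bias ``I`` are
the "templates" — the only trainable parameters.  Out-of-grid neighbors
contribute zero to both sums (virtual boundary cells with ``u = y = 0``).

Inference integrates the state ODE by forward Euler from ``x(0) = 0`` until
the dynamics reach a steady state (or a step cap), then returns the
saturated output of the final state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Neighborhood",
    "TemplateSet",
    "IntegrationConfig",
    "DivergenceError",
    "saturating_output",
    "state_derivative",
    "infer",
    "infer_batch",
]

#: guard against runaway dynamics: any |x| above this aborts integration
OVERFLOW_GUARD = 1e6

try:  # optional JIT acceleration of the Euler loop; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Neighborhood(Enum):
    """Coupling footprint of a cell: all 8 surrounding cells or only the
    4 edge-adjacent ones (corner template weights pinned to zero)."""

    EIGHT = 8
    FOUR = 4

    @property
    def mask(self) -> np.ndarray:
        """3x3 boolean mask of active template positions."""
        if self is Neighborhood.EIGHT:
            return np.ones((3, 3), dtype=bool)
        m = np.zeros((3, 3), dtype=bool)
        m[1, :] = True
        m[:, 1] = True
        return m


def _as_template_matrix(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (3, 3):
        raise ValueError(f"template matrix must be 3x3, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("template matrix contains non-finite entries")
    return a


@dataclass
class TemplateSet:
    """The trainable parameters: feedback matrix A, control matrix B, bias I.

    All 19 scalars (9 + 9 + 1) are shared by every cell of the grid.
    """

    A: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    B: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    I: float = 0.0

    def __post_init__(self) -> None:
        self.A = _as_template_matrix(self.A)
        self.B = _as_template_matrix(self.B)
        self.I = float(self.I)
        if not np.isfinite(self.I):
            raise ValueError("bias I is non-finite")

    def copy(self) -> "TemplateSet":
        return TemplateSet(self.A.copy(), self.B.copy(), self.I)

    def masked(self, nb: Neighborhood) -> "TemplateSet":
        """Return a copy with inactive (corner) positions zeroed."""
        m = nb.mask
        return TemplateSet(np.where(m, self.A, 0.0), np.where(m, self.B, 0.0), self.I)

    def clipped(self, lo: float, hi: float) -> "TemplateSet":
        return TemplateSet(
            np.clip(self.A, lo, hi), np.clip(self.B, lo, hi),
            float(np.clip(self.I, lo, hi)),
        )

    def flat(self) -> np.ndarray:
        """All 19 parameters as a vector (A row-major, B row-major, I)."""
        return np.concatenate([self.A.ravel(), self.B.ravel(), [self.I]])

    @classmethod
    def from_flat(cls, v: np.ndarray) -> "TemplateSet":
        v = np.asarray(v, dtype=float)
        if v.shape != (19,):
            raise ValueError("flat template vector must have 19 entries")
        return cls(v[:9].reshape(3, 3), v[9:18].reshape(3, 3), float(v[18]))

    def allclose(self, other: "TemplateSet", **kw) -> bool:
        return bool(
            np.allclose(self.A, other.A, **kw)
            and np.allclose(self.B, other.B, **kw)
            and np.isclose(self.I, other.I, **kw)
        )


@dataclass(frozen=True)
class IntegrationConfig:
    """Forward-Euler settings for running the state ODE to steady state.

    ``dt * max_steps`` must be large enough that the uncoupled system
    (zero templates, pure -x decay) settles below ``steady_tol``:
    with the defaults the horizon is dt*max_steps = 15 time constants
    (pure decay reaches ~3e-7 of its initial value, well under the
    default tolerance).
    """

    dt: float = 0.25
    max_steps: int = 60
    steady_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.steady_tol < 0:
            raise ValueError("steady_tol must be >= 0")


class DivergenceError(RuntimeError):
    """Raised when the state dynamics blow past the overflow guard."""


def saturating_output(x: np.ndarray) -> np.ndarray:
    """Cell output y = 1/2 (|x+1| - |x-1|): identity on [-1, 1], saturating
    at +/-1 outside.  Elementwise over any array shape."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite cell state at index {idx}")
    # final clip guards against 1-ulp overshoot of the float subtraction
    return np.clip(0.5 * (np.abs(x + 1.0) - np.abs(x - 1.0)), -1.0, 1.0)


def _conv3x3(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate the trailing two axes of ``grid`` with a 3x3 kernel,
    zero boundary.  Supports leading batch axes; kernel index (m,n)
    multiplies grid value at (i+m-2, j+n-2) — the template convention."""
    pad = [(0, 0)] * (grid.ndim - 2) + [(1, 1), (1, 1)]
    g = np.pad(grid, pad)
    out = np.zeros_like(grid)
    h, w = grid.shape[-2], grid.shape[-1]
    for m in range(3):
        for n in range(3):
            k = kernel[m, n]
            if k != 0.0:
                out += k * g[..., m : m + h, n : n + w]
    return out


def state_derivative(
    x: np.ndarray,
    u: np.ndarray,
    theta: TemplateSet,
    nb: Neighborhood = Neighborhood.EIGHT,
) -> np.ndarray:
    """dx/dt = -x + A*y + B*u + I with zero-boundary 3x3 coupling.

    ``x`` and ``u`` may carry leading batch axes; shapes must agree.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != u.shape:
        raise ValueError(f"state shape {x.shape} != input shape {u.shape}")
    th = theta.masked(nb)
    y = saturating_output(x)
    return -x + _conv3x3(y, th.A) + _conv3x3(u, th.B) + th.I


if _HAVE_NUMBA:

    # no fastmath: strict IEEE ordering keeps trajectories bit-reproducible
    # across machines
    @_njit(cache=False)
    def _euler_kernel(U, A, B, I, dt, max_steps, tol, guard):  # pragma: no cover
        nb, H, W = U.shape
        drive = np.empty_like(U)
        for b in range(nb):
            for i in range(H):
                for j in range(W):
                    s = I
                    for m in range(3):
                        ii = i + m - 1
                        if ii < 0 or ii >= H:
                            continue
                        for n in range(3):
                            jj = j + n - 1
                            if jj < 0 or jj >= W:
                                continue
                            s += B[m, n] * U[b, ii, jj]
                    drive[b, i, j] = s
        x = np.zeros_like(U)
        xn = np.empty_like(U)
        yp = np.zeros((nb, H + 2, W + 2))  # saturated outputs, zero border
        feedback = False
        for m in range(3):
            for n in range(3):
                if A[m, n] != 0.0:
                    feedback = True
        status = 0
        steps = 0
        for step in range(max_steps):
            maxdx = 0.0
            maxx = 0.0
            if feedback:
                for b in range(nb):
                    for i in range(H):
                        for j in range(W):
                            xv = x[b, i, j]
                            yp[b, i + 1, j + 1] = 0.5 * (abs(xv + 1.0) - abs(xv - 1.0))
                for b in range(nb):
                    for i in range(H):
                        for j in range(W):
                            s = drive[b, i, j] - x[b, i, j]
                            for m in range(3):
                                for n in range(3):
                                    a = A[m, n]
                                    if a != 0.0:
                                        s += a * yp[b, i + m, j + n]
                            xn[b, i, j] = x[b, i, j] + dt * s
                            ds = abs(s)
                            if ds > maxdx:
                                maxdx = ds
                            av = abs(xn[b, i, j])
                            if av > maxx:
                                maxx = av
            else:
                for b in range(nb):
                    for i in range(H):
                        for j in range(W):
                            s = drive[b, i, j] - x[b, i, j]
                            xn[b, i, j] = x[b, i, j] + dt * s
                            ds = abs(s)
                            if ds > maxdx:
                                maxdx = ds
                            av = abs(xn[b, i, j])
                            if av > maxx:
                                maxx = av
            x, xn = xn, x
            steps = step + 1
            if maxx > guard:
                status = 1
                break
            if maxdx < tol:
                break
        return x, steps, status


def infer_batch(
    u: np.ndarray,
    theta: TemplateSet,
    nb: Neighborhood = Neighborhood.EIGHT,
    cfg: IntegrationConfig | None = None,
) -> np.ndarray:
    """Run the CNN to steady state on a stack of input maps at once.

    ``u`` has shape (..., H, W); all maps share the templates and are
    integrated jointly (the early-stop test is the max |dx/dt| over the
    whole stack).  Returns the saturated outputs, same shape as ``u``.
    """
    if cfg is None:
        cfg = IntegrationConfig()
    u = np.asarray(u, dtype=float)
    if u.shape[-2] < 3 or u.shape[-1] < 3:
        raise ValueError("input grid must be at least 3x3")
    th = theta.masked(nb)

    if _HAVE_NUMBA:
        lead = u.shape[:-2]
        flat = np.ascontiguousarray(u.reshape((-1,) + u.shape[-2:]))
        x, steps, status = _euler_kernel(
            flat, th.A, th.B, th.I,
            cfg.dt, cfg.max_steps, cfg.steady_tol, OVERFLOW_GUARD,
        )
        if status == 1:
            cell = np.unravel_index(int(np.argmax(np.abs(x))), x.shape)
            raise DivergenceError(
                f"state overflow (|x| > {OVERFLOW_GUARD:g}) at step {steps - 1}, "
                f"cell {tuple(int(c) for c in cell)}"
            )
        return saturating_output(x.reshape(lead + u.shape[-2:]))

    # numpy fallback: same forward-Euler scheme
    drive = _conv3x3(u, th.B) + th.I
    x = np.zeros_like(u)
    feedback = np.any(th.A != 0.0)
    for step in range(cfg.max_steps):
        y = 0.5 * (np.abs(x + 1.0) - np.abs(x - 1.0))
        dx = (_conv3x3(y, th.A) + drive - x) if feedback else (drive - x)
        x = x + cfg.dt * dx
        amax = np.max(np.abs(x))
        if amax > OVERFLOW_GUARD:
            cell = np.unravel_index(int(np.argmax(np.abs(x))), x.shape)
            raise DivergenceError(
                f"state overflow (|x| > {OVERFLOW_GUARD:g}) at step {step}, "
                f"cell {tuple(int(c) for c in cell)}"
            )
        if np.max(np.abs(dx)) < cfg.steady_tol:
            break
    return saturating_output(x)


def infer(
    u: np.ndarray,
    theta: TemplateSet,
    nb: Neighborhood = Neighborhood.EIGHT,
    cfg: IntegrationConfig | None = None,
) -> np.ndarray:
    """Steady-state CNN output for a single H x W input map."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("infer expects a single 2-D input map")
    return infer_batch(u, theta, nb, cfg)
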