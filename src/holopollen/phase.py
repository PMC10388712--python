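"""Phase extraction, 2D unwrapping and background flattening.

The reconstructed complex field yields only the wrapped phase (the
four-quadrant arctangent of imaginary over real parts, in (-π, π]). The
continuous phase surface is recovered by a transport-of-intensity /
Poisson approach: wrapped phase gradients estimated through the complex
exponential are residue-free by construction, their divergence gives a
Laplacian estimate, and the Poisson equation is solved with a discrete
cosine transform under Neumann boundary conditions (free edges of the
field of view). A final congruence step snaps the least-squares solution
back onto the wrapped data modulo 2π.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import fft as spfft

from .simulate import ComplexField, OpticsMeta

__all__ = ["PhaseState", "PhaseMap", "wrap_phase", "unwrap_tie", "remove_background"]

logger = logging.getLogger(__name__)


class PhaseState(str, Enum):
    WRAPPED = "wrapped"
    UNWRAPPED = "unwrapped"


@dataclass
class PhaseMap:
    """2D phase image in radians with wrapped/unwrapped bookkeeping."""

    values: np.ndarray
    state: PhaseState = PhaseState.WRAPPED
    meta: OpticsMeta = field(default_factory=OpticsMeta)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PhaseMap expects a 2D array")
        if self.state is PhaseState.WRAPPED:
            v = self.values
            if v.size and (v.min() <= -np.pi or v.max() > np.pi):
                raise ValueError("wrapped phase must lie in (-pi, pi]")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("unwrapped phase must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _to_half_open(values: np.ndarray) -> np.ndarray:
    """Map angles into the half-open interval (-π, π]."""
    out = np.mod(values + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def wrap_phase(fld: ComplexField | np.ndarray, meta: OpticsMeta | None = None) -> PhaseMap:
    """Wrapped phase of a complex field: atan2(imag, real) in (-π, π].

    Exactly-zero pixels have undefined phase; they are set to 0 and a
    warning is logged (downstream masks should exclude them).
    """
    values = fld.values if isinstance(fld, ComplexField) else np.asarray(fld, dtype=complex)
    zeros = values == 0
    if np.any(zeros):
        logger.warning("wrap_phase: %d zero-amplitude pixels set to phase 0", int(zeros.sum()))
    phase = np.arctan2(values.imag, values.real)
    phase = _to_half_open(phase)
    phase[zeros] = 0.0
    return PhaseMap(values=phase, state=PhaseState.WRAPPED, meta=meta or OpticsMeta())


def _poisson_solve_neumann(rho: np.ndarray) -> np.ndarray:
    """Solve ∇²u = rho with Neumann boundaries via DCT-II diagonalization."""
    m, n = rho.shape
    rho_hat = spfft.dctn(rho, type=2, norm="ortho")
    kr = np.arange(m)[:, None]
    kc = np.arange(n)[None, :]
    denom = 2.0 * (np.cos(np.pi * kr / m) - 1.0) + 2.0 * (np.cos(np.pi * kc / n) - 1.0)
    denom[0, 0] = 1.0  # the mean of u is unconstrained; pin it to zero
    u_hat = rho_hat / denom
    u_hat[0, 0] = 0.0
    return spfft.idctn(u_hat, type=2, norm="ortho")


def unwrap_tie(wrapped: PhaseMap, congruent: bool = True) -> PhaseMap:
    """Unwrap a 2D phase map by the Poisson (transport-of-intensity) method.

    Wrapped pixel-to-pixel gradients are computed through the complex
    exponential of the phase (so they are insensitive to 2π jumps), their
    divergence forms the Laplacian estimate, and the Poisson equation is
    solved with a Neumann-boundary DCT solver. With ``congruent=True`` the
    least-squares surface is shifted pixel-wise by the nearest 2π multiple
    so the output agrees with the wrapped input modulo 2π. The result is
    unique up to a global additive 2π·k.
    """
    if wrapped.state is not PhaseState.WRAPPED:
        raise ValueError("unwrap_tie expects a wrapped PhaseMap")
    psi = wrapped.values
    expp = np.exp(1j * psi)
    # wrapped forward differences (zero on the replicate boundary)
    dr = np.zeros_like(psi)
    dc = np.zeros_like(psi)
    dr[:-1, :] = np.angle(expp[1:, :] * np.conj(expp[:-1, :]))
    dc[:, :-1] = np.angle(expp[:, 1:] * np.conj(expp[:, :-1]))
    # divergence (backward difference) of the wrapped gradient field
    rho = np.zeros_like(psi)
    rho += dr
    rho[1:, :] -= dr[:-1, :]
    rho += dc
    rho[:, 1:] -= dc[:, :-1]
    u = _poisson_solve_neumann(rho)
    if congruent:
        k = np.round((u - psi) / (2 * np.pi))
        u = psi + 2 * np.pi * k
    return PhaseMap(values=u, state=PhaseState.UNWRAPPED, meta=wrapped.meta)


class InsufficientBackgroundError(ValueError):
    """Too few background pixels to fit the background plane."""


def remove_background(
    phase: PhaseMap,
    background_mask: np.ndarray | None = None,
    min_background_px: int = 100,
) -> PhaseMap:
    """Subtract a least-squares background plane from an unwrapped phase map.

    The plane (offset + row/col tilts) is fitted over the background
    region — the complement of ``background_mask`` when given, else a
    border frame — then subtracted everywhere; a final offset makes the
    background median exactly zero.
    """
    if phase.state is not PhaseState.UNWRAPPED:
        raise ValueError("remove_background expects an unwrapped PhaseMap")
    v = phase.values
    if background_mask is not None:
        bg = ~np.asarray(background_mask, dtype=bool)
    else:
        b = max(4, min(v.shape) // 16)
        bg = np.zeros(v.shape, dtype=bool)
        bg[:b, :] = bg[-b:, :] = True
        bg[:, :b] = bg[:, -b:] = True
    n_bg = int(bg.sum())
    if n_bg < min_background_px:
        raise InsufficientBackgroundError(
            f"only {n_bg} background pixels available (need >= {min_background_px})"
        )
    rows, cols = np.indices(v.shape)
    A = np.column_stack([np.ones(n_bg), rows[bg], cols[bg]])
    coef, *_ = np.linalg.lstsq(A, v[bg], rcond=None)
    plane = coef[0] + coef[1] * rows + coef[2] * cols
    out = v - plane
    out = out - np.median(out[bg])
    return PhaseMap(values=out, state=PhaseState.UNWRAPPED, meta=phase.meta)
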