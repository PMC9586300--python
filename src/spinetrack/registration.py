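"""Translation registration of session stacks to the day-11 baseline.

Chronic-window fields move by small rigid translations between sessions, so
a translation-only model is used: the integer-voxel shift maximizing the
normalized cross-correlation (computed via FFT, restricted to a configured
bound) followed by quadratic sub-voxel refinement in the lateral axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ImageStack

__all__ = ["RegistrationResult", "RegistrationError", "register_to_baseline"]


class RegistrationError(RuntimeError):
    """Correlation peak too weak to trust the alignment."""


@dataclass(frozen=True)
class RegistrationResult:
    """Recovered translation (um, x/y/z) of a session relative to baseline.

    A scene feature at position p in the baseline appears at p + translation
    in the session stack; subtract ``translation_um`` from session
    coordinates to map them into the baseline frame.
    """

    session_day: int
    translation_um: tuple[float, float, float]
    score: float

    @property
    def offset_xyz(self) -> np.ndarray:
        return np.asarray(self.translation_um, dtype=float)


IDENTITY = None  # sentinel used by callers for the baseline session


def _quadratic_peak(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a local maximum; keep the integer peak
        return 0.0
    delta = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(delta, -0.5, 0.5))


def register_to_baseline(
    stack: ImageStack,
    baseline: ImageStack,
    max_shift_um: float = 5.0,
    min_score: float = 0.2,
) -> RegistrationResult:
    """Register one session stack to the baseline stack.

    Deterministic.  Raises ``RegistrationError`` when the best Pearson
    correlation over the search window falls below ``min_score`` (e.g. a
    pure-noise pair).
    """
    if stack.voxels.shape != baseline.voxels.shape or stack.sampling != baseline.sampling:
        raise ValueError("stacks must share shape and voxel geometry")
    a = stack.voxels.astype(np.float64) - float(stack.voxels.mean())
    b = baseline.voxels.astype(np.float64) - float(baseline.voxels.mean())
    # circular cross-correlation c[s] = sum_p a[p] b[p - s]: peak at the
    # translation of the session scene relative to baseline
    fa = np.fft.rfftn(a)
    fb = np.fft.rfftn(b)
    c = np.fft.irfftn(fa * np.conj(fb), s=a.shape, axes=(0, 1, 2))

    samp = np.asarray(stack.sampling)  # (z, y, x)
    bound = np.minimum(
        np.floor(max_shift_um / samp).astype(int),
        np.asarray(a.shape) // 2 - 1,
    )
    lags = [np.r_[0 : bound[k] + 1, -bound[k] : 0] if bound[k] > 0 else np.array([0]) for k in range(3)]
    win = c[np.ix_(*lags)]
    peak = np.unravel_index(int(np.argmax(win)), win.shape)
    int_shift = np.array([lags[k][peak[k]] for k in range(3)])  # (z, y, x) voxels

    # Pearson score at the integer shift (wrap overlap)
    b_shift = np.roll(b, int_shift, axis=(0, 1, 2))
    na, nb = np.linalg.norm(a), np.linalg.norm(b_shift)
    score = float((a * b_shift).sum() / (na * nb)) if na > 0 and nb > 0 else 0.0
    if score < min_score:
        raise RegistrationError(
            f"registration failed: peak correlation {score:.3f} < {min_score} "
            f"at shift {tuple(int_shift)} voxels (day {stack.session_day})"
        )

    # quadratic sub-voxel refinement in the lateral (y, x) axes
    shift = int_shift.astype(float)
    for axis in (1, 2):
        idx = list(int_shift)
        cm = []
        for d in (-1, 0, 1):
            idx_d = idx.copy()
            idx_d[axis] = (idx[axis] + d) % a.shape[axis]
            cm.append(c[tuple(np.mod(idx_d, a.shape))])
        shift[axis] += _quadratic_peak(*cm)

    translation = (
        float(shift[2] * samp[2]),
        float(shift[1] * samp[1]),
        float(shift[0] * samp[0]),
    )
    return RegistrationResult(stack.session_day, translation, score)
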