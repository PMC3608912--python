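"""Glass-pattern stimulus generation.

A Glass pattern is a field of dot pairs (*dipoles*).  Each signal dipole is
oriented at a fixed *spiral angle* to the radius joining its centre to the
centre of the aperture: 0 deg gives a radial pattern, 90 deg a concentric
one, and intermediate angles spirals.  Stimulus strength is controlled by
the *signal level*: the percentage of dipoles that follow the spiral rule,
the remainder being assigned uniformly random orientations.

Geometry defaults follow the experimental convention of a 7.7 deg square
aperture, 3% dot density, 2.3 arcmin square dots and a dipole dot
separation ("Glass shift") of 16.2 arcmin (25 arcmin for training stimuli,
30 arcmin for test/scanning stimuli).  All coordinates are in arcmin
relative to the aperture centre; orientations are in degrees modulo 180
(dipoles are unoriented segments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GlassPatternSpec", "GlassPattern", "spiral_orientation",
           "generate_pattern", "render"]


@dataclass(frozen=True)
class GlassPatternSpec:
    """Parametric description of one Glass-pattern stimulus."""

    aperture_deg: float = 7.7
    dot_density: float = 0.03
    glass_shift_arcmin: float = 16.2
    dot_size_arcmin: float = 2.3
    spiral_angle_deg: float = 0.0          # 0 radial, 90 concentric
    handedness: str = "clockwise"          # anticlockwise negates the angle
    exemplar_jitter_deg: float = 5.0       # per-stimulus jitter half-width
    condition_jitter_deg: float = 1.5      # per-trial jitter half-width
    signal_level_pct: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_level_pct <= 100.0:
            raise ValueError("signal_level_pct must lie in [0, 100]")
        if not 0.0 < self.dot_density < 1.0:
            raise ValueError("dot_density must lie in (0, 1)")
        if self.glass_shift_arcmin <= self.dot_size_arcmin:
            raise ValueError("glass_shift_arcmin must exceed dot_size_arcmin")
        if self.handedness not in ("clockwise", "anticlockwise"):
            raise ValueError("handedness must be clockwise|anticlockwise")

    @property
    def aperture_arcmin(self) -> float:
        return self.aperture_deg * 60.0

    @property
    def n_dipoles(self) -> int:
        """round(density * aperture_area / (2 * dot_area)) dipoles."""
        area = self.aperture_arcmin ** 2
        dot_area = self.dot_size_arcmin ** 2
        return int(round(self.dot_density * area / (2.0 * dot_area)))

    @property
    def signed_spiral_angle(self) -> float:
        return (self.spiral_angle_deg if self.handedness == "clockwise"
                else -self.spiral_angle_deg)

    def with_signal(self, signal_level_pct: float) -> "GlassPatternSpec":
        return replace(self, signal_level_pct=signal_level_pct)


@dataclass
class GlassPattern:
    """Realised dipole field: centres (arcmin), orientations (deg mod 180)."""

    centers: np.ndarray            # (n, 2) xy arcmin, aperture-centred
    orientations: np.ndarray       # (n,) degrees in [0, 180)
    is_signal: np.ndarray          # (n,) bool
    template_angle_deg: float      # jittered spiral angle actually used
    spec: GlassPatternSpec = field(repr=False, default=None)

    @property
    def n_dipoles(self) -> int:
        return len(self.centers)

    def dot_positions(self) -> np.ndarray:
        """The two dot centres per dipole, shape (n, 2, 2)."""
        theta = np.deg2rad(self.orientations)
        half = 0.5 * self.spec.glass_shift_arcmin
        d = np.stack([np.cos(theta), np.sin(theta)], axis=1) * half
        return np.stack([self.centers + d, self.centers - d], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_arcmin": self.centers[:, 0],
            "y_arcmin": self.centers[:, 1],
            "orientation_deg": self.orientations,
            "is_signal": self.is_signal.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def spiral_orientation(dipole_center, spiral_angle_deg: float) -> float:
    """Orientation (deg mod 180) of a dipole obeying the spiral rule.

    The dipole is oriented at ``spiral_angle_deg`` to the radius from the
    aperture centre to the dipole centre: the local radial direction angle
    plus the spiral angle, modulo 180.
    """
    x, y = float(dipole_center[0]), float(dipole_center[1])
    if x == 0.0 and y == 0.0:
        raise ValueError("dipole at aperture centre: radial direction undefined")
    radial = np.degrees(np.arctan2(y, x))
    return float((radial + spiral_angle_deg) % 180.0)


def generate_pattern(spec: GlassPatternSpec,
                     rng: np.random.Generator | None = None,
                     max_tries_per_dipole: int = 200) -> GlassPattern:
    """Generate a fresh dipole layout for one stimulus presentation.

    Dipole centres are drawn uniformly with rejection so that both dots of
    the dipole fall entirely inside the aperture; exactly
    ``round(n * signal / 100)`` dipoles follow the (jittered) spiral
    template, the remainder get uniformly random orientations.  Condition
    jitter (one draw) and exemplar jitter (one draw) are both applied to the
    template angle before orienting signal dipoles.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_dipoles
    n_signal = int(round(n * spec.signal_level_pct / 100.0))
    half_ap = spec.aperture_arcmin / 2.0
    half_dot = spec.dot_size_arcmin / 2.0
    half_shift = spec.glass_shift_arcmin / 2.0

    cond_j = rng.uniform(-spec.condition_jitter_deg, spec.condition_jitter_deg)
    exem_j = rng.uniform(-spec.exemplar_jitter_deg, spec.exemplar_jitter_deg)
    template = spec.signed_spiral_angle + cond_j + exem_j

    centers = np.empty((n, 2))
    orientations = np.empty(n)
    is_signal = np.zeros(n, bool)
    is_signal[:n_signal] = True

    for i in range(n):
        for _ in range(max_tries_per_dipole):
            c = rng.uniform(-half_ap, half_ap, size=2)
            if c[0] == 0.0 and c[1] == 0.0:
                continue  # degenerate: radial direction undefined
            if is_signal[i]:
                ori = spiral_orientation(c, template) % 180.0
            else:
                ori = rng.uniform(0.0, 180.0)
            th = np.deg2rad(ori)
            offs = np.array([np.cos(th), np.sin(th)]) * half_shift
            ok = True
            for dot in (c + offs, c - offs):
                if np.any(np.abs(dot) + half_dot > half_ap):
                    ok = False
                    break
            if ok:
                centers[i] = c
                orientations[i] = ori
                break
        else:
            raise RuntimeError(
                "dipole placement failed repeatedly; spec infeasible "
                "(density/shift too large for the aperture)"
            )
    # signal dipoles first would leave a spatial artifact only if position
    # depended on signal status; it does not, but shuffle for tidiness
    perm = rng.permutation(n)
    return GlassPattern(centers[perm], orientations[perm], is_signal[perm],
                        template_angle_deg=float(template % 180.0), spec=spec)


def render(pattern: GlassPattern, px_per_deg: float = 30.0) -> np.ndarray:
    """Rasterise to a binary image: white square dots on black, origin at centre.

    Rows index y (bottom-up in stimulus coordinates), columns x.  Emits a
    warning when the resolution cannot separate the two dots of a dipole.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    spec = pattern.spec
    ppa = px_per_deg / 60.0  # pixels per arcmin
    if spec.glass_shift_arcmin * ppa < 2.0:
        warnings.warn("resolution too low to separate the dots of a dipole")
    side = int(round(spec.aperture_deg * px_per_deg))
    img = np.zeros((side, side), dtype=np.uint8)
    if pattern.n_dipoles == 0:
        return img
    # fixed integer dot width keeps the rendered area faithful to dot_size
    w = max(1, int(round(spec.dot_size_arcmin * ppa)))
    dots = pattern.dot_positions().reshape(-1, 2) * ppa + side / 2.0
    for cx, cy in dots:
        x0 = int(round(cx - w / 2.0))
        y0 = int(round(cy - w / 2.0))
        img[max(y0, 0):min(y0 + w, side), max(x0, 0):min(x0 + w, side)] = 1
    return img


def save_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)
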