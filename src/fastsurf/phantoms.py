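"""Synthetic phantom label volumes.

Analytic solids (sphere, ellipsoid, cylinder, box) with closed-form volumes,
and a hippocampus-like phantom: an elliptical cross-section swept along a
planar C-shaped centerline with a monotone head-to-tail taper, rasterised at
MRI-like 1 x 1 x 1.2 mm voxels.  Default sizes put the phantom at ~20
occupied slices along its long axis and ~2.4 cm^3, the regime of manually
outlined hippocampi.

Randomness (boundary jitter, used to emulate independent re-delineations of
back-to-back scans) is band-limited — low-order Fourier modes over the
tube's angular and longitudinal coordinates — so phantoms stay smooth, and
is fully determined by the spec's integer seed.  Atrophic follow-up
phantoms shrink the cross-section radii by sqrt(1 - f) at fixed length, so
the underlying (pre-rasterisation) volume loss is exactly the requested
fraction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SpecError
from .geometry import LabelVolume

__all__ = ["PhantomSpec", "make_phantom", "make_btb_pair", "make_atrophy_pair"]

_KINDS = ("sphere", "ellipsoid", "cylinder", "box", "hippocampus")

# jitter modes: (angular harmonic k >= 1, longitudinal harmonic l)
_JITTER_MODES = [(k, l) for k in (1, 2, 3) for l in (0, 1, 2)]


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description; identical spec + seed gives a
    bit-identical volume.

    ``size`` is kind-specific, in mm: sphere (r,), ellipsoid (a, b, c) semi-
    axes, cylinder (r, h), box (lx, ly, lz); for the hippocampus phantom it
    is (head_radius, length) of the swept tube.
    """

    kind: str = "hippocampus"
    size: tuple = (10.5, 23.0)
    spacing: tuple = (1.0, 1.0, 1.2)
    axis: int = 2  # long / slicing axis of the phantom
    bend_deg: float = 40.0  # total C-shape bend of the centerline
    taper: float = 0.6  # tail/head cross-section radius ratio
    ellipticity: float = 0.62  # minor/major cross-section axis ratio
    sigma: float = 0.0  # boundary jitter amplitude, mm
    atrophy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SpecError(f"unknown phantom kind {self.kind!r}")
        if any(s <= 0 for s in self.size) or any(s <= 0 for s in self.spacing):
            raise SpecError("sizes and voxel spacing must be positive")
        if not 0.0 <= self.atrophy_fraction <= 0.5:
            raise SpecError("atrophy_fraction must lie in [0, 0.5]")
        if self.sigma < 0:
            raise SpecError("jitter sigma must be >= 0")
        if self.axis not in (0, 1, 2):
            raise SpecError("axis must be 0, 1 or 2")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["size"] = tuple(d["size"])
        d["spacing"] = tuple(d["spacing"])
        return cls(**d)


# ---------------------------------------------------------------------------
# implicit shapes
# ---------------------------------------------------------------------------


def _solid_membership(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if spec.kind == "sphere":
        (r,) = spec.size
        return x * x + y * y + z * z <= r * r
    if spec.kind == "ellipsoid":
        a, b, c = spec.size
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if spec.kind == "cylinder":
        r, h = spec.size
        ax = spec.axis
        inplane = [d for d in range(3) if d != ax]
        rad2 = pts[:, inplane[0]] ** 2 + pts[:, inplane[1]] ** 2
        return (rad2 <= r * r) & (np.abs(pts[:, ax]) <= h / 2)
    if spec.kind == "box":
        lx, ly, lz = spec.size
        return (
            (np.abs(x) <= lx / 2) & (np.abs(y) <= ly / 2) & (np.abs(z) <= lz / 2)
        )
    raise SpecError(spec.kind)


def _solid_volume(spec: PhantomSpec) -> float:
    if spec.kind == "sphere":
        return 4.0 / 3.0 * np.pi * spec.size[0] ** 3
    if spec.kind == "ellipsoid":
        a, b, c = spec.size
        return 4.0 / 3.0 * np.pi * a * b * c
    if spec.kind == "cylinder":
        r, h = spec.size
        return np.pi * r * r * h
    if spec.kind == "box":
        lx, ly, lz = spec.size
        return lx * ly * lz
    raise SpecError(spec.kind)


def _solid_extent(spec: PhantomSpec) -> np.ndarray:
    """Half-extent of the solid along each world axis."""
    if spec.kind == "sphere":
        return np.full(3, spec.size[0])
    if spec.kind == "ellipsoid":
        return np.asarray(spec.size, dtype=float)
    if spec.kind == "cylinder":
        r, h = spec.size
        ext = np.full(3, r)
        ext[spec.axis] = h / 2
        return ext
    if spec.kind == "box":
        return np.asarray(spec.size, dtype=float) / 2
    raise SpecError(spec.kind)


def _jitter_coeffs(seed: int) -> np.ndarray:
    """(M, 2) cos/sin coefficients for the band-limited boundary jitter,
    normalised to unit RMS over (theta, t)."""
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal((len(_JITTER_MODES), 2))
    # each term a*cos(k th)*cos(l pi t + phi) has RMS 1/2 (1/sqrt(2) per factor)
    norm = np.sqrt(np.sum(coeffs**2) / 4.0)
    phases = rng.uniform(0, 2 * np.pi, len(_JITTER_MODES))
    return coeffs / max(norm, 1e-12), phases


def _jitter(theta, t, sigma, seed):
    if sigma == 0:
        return 0.0
    coeffs, phases = _jitter_coeffs(seed)
    out = np.zeros_like(np.broadcast_arrays(theta, t)[0], dtype=float)
    for (k, l), (a, b), phi in zip(_JITTER_MODES, coeffs, phases):
        ang = a * np.cos(k * theta) + b * np.sin(k * theta)
        out += ang * np.cos(l * np.pi * t + phi)
    return sigma * out


def _hippo_major_radius(spec: PhantomSpec, t) -> np.ndarray:
    """Major cross-section semi-axis along the sweep parameter t in [0, 1].

    Linear head-to-tail taper modulated by an elliptic longitudinal profile
    so the structure rounds off toward both extreme slices (a cut-off tube
    would put the largest contour on an end slice, which manual outlining
    protocols do not produce)."""
    a_head, _ = spec.size
    rounded = np.sqrt(np.clip(1.0 - ((t - 0.5) / 0.54) ** 2, 0.0, None))
    return a_head * (1.0 - (1.0 - spec.taper) * t) * rounded


def _hippo_membership(spec: PhantomSpec, pts: np.ndarray, scale_xy: float) -> np.ndarray:
    """Membership of points in the swept-tube phantom.

    Cross-sections are defined in the slice plane (perpendicular to the
    long axis), centred on a bowed centerline, with tapered, end-rounded
    radii; the sweep parameter t runs 0 (head) to 1 (tail).
    """
    a_head, length = spec.size
    ax = spec.axis
    inplane = [d for d in range(3) if d != ax]
    s = pts[:, ax]
    t = s / length + 0.5
    in_span = (t >= 0.0) & (t <= 1.0)
    tc = np.clip(t, 0.0, 1.0)
    bow = _bow_amplitude(spec)
    cx = bow * np.sin(np.pi * tc)
    a = np.maximum(_hippo_major_radius(spec, tc), 1e-9) * scale_xy
    b = spec.ellipticity * a
    dx = pts[:, inplane[0]] - cx
    dy = pts[:, inplane[1]]
    m = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    if spec.sigma > 0:
        theta = np.arctan2(dy, dx)
        rho = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        m_limit = 1.0 + _jitter(theta, tc, spec.sigma, spec.seed) / rho
    else:
        m_limit = 1.0
    return in_span & (m <= m_limit)


def _bow_amplitude(spec: PhantomSpec) -> float:
    """Lateral centerline offset giving the requested total bend angle.

    For x(t) = A sin(pi t) over a tube of given length, the tangent angle at
    the ends is atan(A pi / L); the total direction change head-to-middle-to-
    tail is twice that.
    """
    _, length = spec.size
    half = np.deg2rad(spec.bend_deg) / 2.0
    return float(np.tan(half) * length / np.pi)


def _hippo_volume(spec: PhantomSpec, scale_xy: float) -> float:
    # continuum volume of the swept tube: V = eps * pi * L * int a(t)^2 dt,
    # evaluated by dense trapezoidal quadrature of the closed-form radius
    _, length = spec.size
    t = np.linspace(0.0, 1.0, 20001)
    a2 = _hippo_major_radius(spec, t) ** 2
    return float(
        np.pi * spec.ellipticity * scale_xy**2 * length * np.trapezoid(a2, t)
    )


def _hippo_extent(spec: PhantomSpec) -> np.ndarray:
    a_head, length = spec.size
    ext = np.empty(3)
    inplane = [d for d in range(3) if d != spec.axis]
    ext[spec.axis] = length / 2
    ext[inplane[0]] = a_head + _bow_amplitude(spec)
    ext[inplane[1]] = a_head * spec.ellipticity
    return ext


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------


def _rasterize(spec: PhantomSpec, followup: bool = False, jitter_seed=None) -> LabelVolume:
    spacing = np.asarray(spec.spacing, dtype=float)
    margin = spec.sigma + 3.0  # mm, keeps jittered boundary off the array edge
    scale_xy = np.sqrt(1.0 - spec.atrophy_fraction) if followup else 1.0
    if spec.kind == "hippocampus":
        ext = _hippo_extent(spec) + margin
    else:
        ext = _solid_extent(spec) + margin
    # odd voxel counts: centres sit at integer multiples of the spacing,
    # symmetric about the world origin
    shape = 2 * np.ceil(ext / spacing).astype(int) + 1
    origin = -(shape - 1) / 2.0 * spacing  # world coords of voxel (0,0,0) centre
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * spacing + origin

    eff = spec if jitter_seed is None else replace(spec, seed=jitter_seed)
    if spec.kind == "hippocampus":
        mask = _hippo_membership(eff, pts, scale_xy)
        analytic = _hippo_volume(spec, scale_xy)
    else:
        mask = _solid_membership(eff, pts)
        analytic = _solid_volume(spec)
    data = mask.reshape(shape).astype(np.uint8)
    vol = LabelVolume(data, affine, meta={"analytic_volume": analytic, "spec": asdict(spec)})
    vol.validate()
    return vol


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterise a phantom spec to a binary label volume.

    The analytic (pre-rasterisation, pre-jitter) volume is stored in
    ``vol.meta['analytic_volume']``.
    """
    return _rasterize(spec)


def make_atrophy_pair(spec: PhantomSpec) -> tuple[LabelVolume, LabelVolume]:
    """Baseline and follow-up phantoms; the follow-up loses exactly
    ``atrophy_fraction`` of the underlying volume (cross-section shrinkage
    at fixed length), co-registered by construction."""
    baseline = _rasterize(spec, followup=False)
    followup = _rasterize(spec, followup=True)
    return baseline, followup


def make_btb_pair(spec: PhantomSpec) -> tuple[LabelVolume, LabelVolume]:
    """Two rasterisations of the same shape with independent boundary
    jitter, emulating independently processed back-to-back scans.

    Requires ``sigma > 0`` (with no jitter the scans would be identical).
    The two jitter streams are derived deterministically from the spec seed.
    """
    if spec.sigma <= 0:
        raise SpecError("back-to-back pairs need sigma > 0")
    seed_a, seed_b = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    a = _rasterize(spec, jitter_seed=int(seed_a))
    b = _rasterize(spec, jitter_seed=int(seed_b))
    return a, b
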