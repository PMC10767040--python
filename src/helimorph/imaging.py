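"""Density rendering, projection, band limiting, noise, and power spectra.

Tube models are rendered as sums of isotropic Gaussian blobs, one per atom,
with amplitude proportional to the atomic scattering weight.  Projections
along a direction perpendicular to the tube axis are computed either by
splatting the (analytically projected) Gaussians directly into the image,
or by line-integrating a rendered 3D volume; the two paths agree within
interpolation tolerance and the first is the fast default.

Image conventions: arrays are indexed [row, col] = [z, x]; the coordinate
origin is the image/volume center (pixel (N-1)/2).  The viewing direction
is +y after rotating the model by the azimuth φ about z; the in-plane
rotation ψ and shifts are applied in the image plane.  Power spectra are
zero-frequency-centered |FFT|²/N so that their sum equals the image energy
(Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import mrc
from .tube import TubeModel

__all__ = [
    "Volume",
    "Image",
    "ImageStack",
    "RenderParams",
    "render_volume",
    "project",
    "band_limit",
    "signal_mask",
    "add_noise",
    "power_spectrum",
    "average_power_spectrum",
    "read_mrc",
    "write_mrc",
]


@dataclass
class Volume:
    """Cubic voxel grid; ``data`` indexed [z, y, x], centered on the origin."""

    data: np.ndarray
    apix: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("volume must be a cubic box")
        if self.apix <= 0:
            raise ValueError("apix must be positive")

    @property
    def box(self) -> int:
        return self.data.shape[0]


@dataclass
class Image:
    """Square pixel grid with metadata (pose, label, seed for synthetics)."""

    data: np.ndarray
    apix: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("image must be square")
        if self.apix <= 0:
            raise ValueError("apix must be positive")

    @property
    def box(self) -> int:
        return self.data.shape[0]


@dataclass
class ImageStack:
    """A stack of same-size, same-apix images."""

    images: list[Image]

    def __post_init__(self) -> None:
        if self.images:
            apix = self.images[0].apix
            box = self.images[0].box
            for im in self.images:
                if im.apix != apix or im.box != box:
                    raise ValueError("stack images must share apix and box")

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> Image:
        return self.images[i]

    @property
    def apix(self) -> float:
        return self.images[0].apix

    def as_array(self) -> np.ndarray:
        return np.stack([im.data for im in self.images])


@dataclass(frozen=True)
class RenderParams:
    """Shared rendering parameters for references and synthetic segments."""

    apix: float = 5.0
    box: int = 128
    blob_sigma: float = 4.0
    resolution: float = 12.0


def render_volume(
    tube: TubeModel,
    apix: float,
    box: int,
    blob_sigma: float = 4.0,
    method: str = "binned",
) -> Volume:
    """Render a tube model as a 3D density volume.

    Density is a sum of isotropic 3D Gaussians (sigma ``blob_sigma`` Å, one
    per atom, amplitude proportional to the scattering weight), normalized
    so the integral over the box equals the total weight of the atoms
    inside it.  ``method='binned'`` deposits trilinear weights and applies
    a Gaussian filter (fast, default); ``'exact'`` evaluates each Gaussian
    on a local window.  Atoms outside the box are clipped with a warning.
    """
    if apix <= 0 or box < 8:
        raise ValueError("require apix > 0 and box >= 8")
    pos = tube.atom_positions()
    wts = tube.atom_weights()
    return _render_points_3d(pos, wts, apix, box, blob_sigma, method)


def _render_points_3d(pos, wts, apix, box, sigma, method) -> Volume:
    import warnings

    half = (box - 1) / 2.0
    # grid index (z, y, x) of each atom
    idx = pos[:, ::-1] / apix + half
    inside = np.all((idx > -4 * sigma / apix) & (idx < box - 1 + 4 * sigma / apix), axis=1)
    if not np.all(inside):
        warnings.warn(f"{np.count_nonzero(~inside)} atoms outside the box were clipped")
        idx, wts = idx[inside], wts[inside]
    grid = np.zeros((box, box, box), dtype=np.float64)
    if method == "binned":
        _deposit_multilinear(grid, idx, wts)
        grid = ndimage.gaussian_filter(grid, _binned_filter_sigma(sigma, apix), truncate=4.0)
        grid /= apix ** 3
    elif method == "exact":
        norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
        r = int(np.ceil(4 * sigma / apix))
        axes = [np.arange(box)] * 3
        for p, w in zip(idx, wts):
            lo = np.maximum(np.floor(p).astype(int) - r, 0)
            hi = np.minimum(np.floor(p).astype(int) + r + 1, box)
            if np.any(lo >= hi):
                continue
            zz = (axes[0][lo[0]:hi[0]] - p[0]) * apix
            yy = (axes[1][lo[1]:hi[1]] - p[1]) * apix
            xx = (axes[2][lo[2]:hi[2]] - p[2]) * apix
            g = np.exp(-0.5 * (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
                               + xx[None, None, :] ** 2) / sigma ** 2)
            grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += w * norm * g
    else:
        raise ValueError(f"unknown render method {method!r}")
    return Volume(grid.astype(np.float32), apix)


def _binned_filter_sigma(sigma: float, apix: float) -> float:
    """Filter width (px) so deposit blur + filter matches a sigma-Å Gaussian.

    The bilinear deposit kernel adds 1/6 px² of variance per axis; the
    Gaussian filter width is reduced to compensate, keeping the composite
    point-spread close to the requested blob sigma.
    """
    var_px = (sigma / apix) ** 2 - 1.0 / 6.0
    return float(np.sqrt(max(var_px, 0.05)))


def _deposit_multilinear(grid: np.ndarray, idx: np.ndarray, wts: np.ndarray) -> None:
    """Deposit point weights with multilinear interpolation (in place)."""
    ndim = grid.ndim
    base = np.floor(idx).astype(int)
    frac = idx - base
    shape = np.array(grid.shape)
    for corner in range(2 ** ndim):
        offs = np.array([(corner >> d) & 1 for d in range(ndim)])
        weight = np.prod(np.where(offs, frac, 1.0 - frac), axis=1) * wts
        coords = base + offs
        ok = np.all((coords >= 0) & (coords < shape), axis=1)
        if not np.any(ok):
            continue
        np.add.at(grid, tuple(coords[ok].T), weight[ok])


def project(
    obj: TubeModel | Volume,
    view: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    apix: float = 5.0,
    box: int = 128,
    blob_sigma: float = 4.0,
    method: str = "exact",
    interp_order: int = 3,
) -> Image:
    """Project a tube model or volume along +y after azimuthal rotation.

    ``view`` is (φ azimuth°, ψ in-plane°, shift_x Å, shift_y Å).  The model
    is rotated by φ about the tube (z) axis and line-integrated along the
    viewing direction +y; ψ rotates and the shifts translate the result in
    the image plane.  For a TubeModel the projected Gaussians are splatted
    analytically (ψ and shifts applied to the 2D atom coordinates, so no
    interpolation); for a Volume the integral is taken over the voxel grid
    and ψ/shifts use spline interpolation of order ``interp_order``
    (cubic by default).
    """
    phi, psi, sx, sy = view
    if not np.all(np.isfinite([phi, psi, sx, sy])):
        raise ValueError("view parameters must be finite")
    if isinstance(obj, TubeModel):
        pos = obj.atom_positions()
        wts = obj.atom_weights()
        c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        x = c * pos[:, 0] - s * pos[:, 1]
        z = pos[:, 2]
        cp, sp = np.cos(np.radians(psi)), np.sin(np.radians(psi))
        u = cp * x - sp * z + sx      # image column coordinate (Å)
        v = sp * x + cp * z + sy      # image row coordinate (Å)
        img = _render_points_2d(np.column_stack([v, u]), wts, apix, box, blob_sigma, method)
        return Image(img, apix, {"phi": phi, "psi": psi, "sx": sx, "sy": sy})
    if isinstance(obj, Volume):
        vol = obj.data.astype(np.float64)
        if phi % 360.0 != 0.0:
            vol = ndimage.rotate(vol, -phi, axes=(2, 1), reshape=False, order=interp_order)
        img = vol.sum(axis=1) * obj.apix  # line integral along y -> [row=z, col=x]
        if psi % 360.0 != 0.0 or sx or sy:
            # same in-plane map as the splat path: (u, v) = R(psi) @ (x, z) + s
            cp, sp = np.cos(np.radians(psi)), np.sin(np.radians(psi))
            half = (img.shape[0] - 1) / 2.0
            sxp, syp = sx / obj.apix, sy / obj.apix
            M = np.array([[cp, -sp], [sp, cp]])  # (row_in, col_in) from (row_out, col_out)
            center = np.array([half, half])
            shift_c = np.array([sp * sxp - cp * syp, -cp * sxp - sp * syp])
            offset = center + shift_c - M @ center
            img = ndimage.affine_transform(img, M, offset=offset, order=interp_order)
        return Image(img.astype(np.float32), obj.apix, {"phi": phi, "psi": psi, "sx": sx, "sy": sy})
    raise TypeError("project expects a TubeModel or Volume")


def _render_points_2d(rc, wts, apix, box, sigma, method) -> np.ndarray:
    half = (box - 1) / 2.0
    idx = rc / apix + half
    grid = np.zeros((box, box), dtype=np.float64)
    if method == "binned":
        keep = np.all((idx > -4 * sigma / apix) & (idx < box - 1 + 4 * sigma / apix), axis=1)
        _deposit_multilinear(grid, idx[keep], wts[keep])
        grid = ndimage.gaussian_filter(grid, _binned_filter_sigma(sigma, apix), truncate=4.0)
        grid /= apix ** 2
    elif method == "exact":
        # vectorized Gaussian evaluation on a (2r+1)² window per atom,
        # accumulated with bincount on flattened pixel indices
        norm = 1.0 / (2.0 * np.pi * sigma ** 2)
        r = int(np.ceil(4 * sigma / apix))
        keep = np.all((idx > -r) & (idx < box - 1 + r), axis=1)
        idx, wts = idx[keep], wts[keep]
        if len(idx):
            offs = np.arange(-r, r + 1)
            base = np.floor(idx).astype(int)
            vv = (base[:, 0, None] + offs[None] - idx[:, 0, None]) * apix
            uu = (base[:, 1, None] + offs[None] - idx[:, 1, None]) * apix
            gv = np.exp(-0.5 * vv ** 2 / sigma ** 2)
            gu = np.exp(-0.5 * uu ** 2 / sigma ** 2)
            g = (wts[:, None, None] * norm) * gv[:, :, None] * gu[:, None, :]
            rows = base[:, 0, None] + offs[None]
            cols = base[:, 1, None] + offs[None]
            ok_r = (rows >= 0) & (rows < box)
            ok_c = (cols >= 0) & (cols < box)
            ok = ok_r[:, :, None] & ok_c[:, None, :]
            flat = (rows[:, :, None] * box + cols[:, None, :])[ok]
            grid += np.bincount(flat, weights=g[ok], minlength=box * box) \
                .reshape(box, box)
    else:
        raise ValueError(f"unknown render method {method!r}")
    return grid.astype(np.float32)


def band_limit(image: Image, resolution: float) -> Image:
    """Hard radial low-pass at 1/resolution (Å⁻¹).

    ``resolution`` must be at least the Nyquist limit 2*apix.
    """
    if resolution < 2.0 * image.apix:
        raise ValueError(
            f"resolution {resolution} Å is beyond Nyquist ({2 * image.apix} Å)"
        )
    n = image.box
    f = np.fft.fftfreq(n, d=image.apix)
    fr = np.fft.rfftfreq(n, d=image.apix)
    mask = (f[:, None] ** 2 + fr[None, :] ** 2) <= (1.0 / resolution) ** 2
    spec = np.fft.rfft2(image.data.astype(np.float64))
    out = np.fft.irfft2(spec * mask, s=(n, n))
    return Image(out.astype(np.float32), image.apix, dict(image.meta, resolution=resolution))


def signal_mask(image: Image, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of pixels carrying signal: |I| > threshold * max|I|."""
    a = np.abs(image.data)
    return a > threshold * a.max()


def add_noise(image: Image, snr: float, seed: int, mask: np.ndarray | None = None) -> Image:
    """Add white Gaussian noise at a given signal-to-noise (variance) ratio.

    The noise variance is var(signal within mask) / snr, where the default
    mask selects pixels with |I| above 5 % of the maximum (the projected
    tube).  The seed fully determines the noise field.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if mask is None:
        mask = signal_mask(image)
    sig_var = float(np.var(image.data[mask]))
    sigma = np.sqrt(sig_var / snr)
    rng = np.random.Generator(np.random.PCG64(seed))
    noise = rng.normal(0.0, sigma, image.data.shape)
    return Image(
        (image.data + noise).astype(np.float32),
        image.apix,
        dict(image.meta, snr=snr, noise_seed=seed, noise_sigma=sigma),
    )


def power_spectrum(image: Image) -> Image:
    """Zero-frequency-centered power spectrum |FFT|²/N (Parseval-normalized)."""
    n = image.box
    spec = np.fft.fftshift(np.fft.fft2(image.data.astype(np.float64)))
    ps = (np.abs(spec) ** 2 / (n * n)).astype(np.float32)
    return Image(ps, image.apix, {"freq_step": 1.0 / (n * image.apix)})


def average_power_spectrum(stack: ImageStack) -> Image:
    """Arithmetic mean of the per-image power spectra."""
    if len(stack) == 0:
        raise ValueError("cannot average an empty stack")
    acc = np.zeros((stack[0].box, stack[0].box), dtype=np.float64)
    for im in stack.images:
        acc += power_spectrum(im).data
    acc /= len(stack)
    return Image(acc.astype(np.float32), stack.apix,
                 {"freq_step": 1.0 / (stack[0].box * stack.apix)})


def write_mrc(obj: Volume | Image | ImageStack, path) -> None:
    """Write a volume, image, or stack as MRC2014 (mode 2, float32)."""
    if isinstance(obj, Volume):
        mrc.write_mrc(obj.data, path, obj.apix, is_stack=False)
    elif isinstance(obj, Image):
        mrc.write_mrc(obj.data, path, obj.apix, is_stack=True)
    elif isinstance(obj, ImageStack):
        mrc.write_mrc(obj.as_array(), path, obj.apix, is_stack=True)
    else:
        raise TypeError("write_mrc expects a Volume, Image, or ImageStack")


def read_mrc(path) -> Volume | ImageStack:
    """Read an MRC2014 file into a Volume (ISPG=1) or ImageStack (ISPG=0)."""
    data, apix, is_stack = mrc.read_mrc(path)
    if is_stack:
        return ImageStack([Image(d, apix) for d in data])
    return Volume(data, apix)
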