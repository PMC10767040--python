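"""Supervised classification of tube segments against a polymorph bank.

A reference bank holds band-limited projections of modeled tubes, one entry
per (n1, n2, flattening scale) hypothesis.  Each segment image is globally
aligned to every entry over a grid of azimuth φ, in-plane rotation ψ, and
integer-pixel shifts; the score is the masked, normalized cross-correlation
(NCC in [-1, 1]) and each segment is assigned to the highest-scoring entry.
Ties are broken deterministically toward the lowest bank key in sorted
order, and the margin to the runner-up is recorded so users can apply their
own confidence cutoffs.

Shift search uses circular FFT cross-correlation (the shift range is capped
at a quarter of the box, so wrap-around touches only masked-out corners or
background).  The same φ rotation of a flattened tube also rotates its
flattening axis relative to the view, so no separate axis-orientation
search is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy import ndimage

from .flattening import flatten
from .imaging import Image, ImageStack, RenderParams, band_limit, project
from .lattice import Lattice2D, helix_from_wrapping, rotational_order
from .tube import AsymmetricUnit, build_tube

logger = logging.getLogger(__name__)

__all__ = [
    "SearchGrid",
    "BankEntry",
    "ReferenceBank",
    "build_reference_bank",
    "align_and_score",
    "classify",
    "summarize",
    "Summary",
]


@dataclass(frozen=True)
class SearchGrid:
    """Alignment search grid.

    φ is sampled over one rotational period of the entry (360°/order for a
    round tube; flattening reduces the order to gcd(order, 2)).  ψ covers
    [-psi_range, +psi_range] — helical segments are extracted with the tube
    axis roughly vertical, so a narrow in-plane search suffices.  Shifts are
    searched on the integer-pixel grid within ±shift_max_frac of the box.
    """

    phi_step: float = 6.0
    psi_range: float = 12.0
    psi_step: float = 4.0
    shift_max_frac: float = 0.25

    def psi_values(self) -> np.ndarray:
        n = int(round(self.psi_range / self.psi_step))
        return np.arange(-n, n + 1) * self.psi_step


@dataclass
class BankEntry:
    """Projections of one (n1, n2, scale) reference over its φ grid."""

    key: tuple[int, int, float]
    projections: np.ndarray  # (n_phi, box, box) float32, band-limited
    phis: np.ndarray
    order: int
    radius: float
    tube: object | None = None  # TubeModel, kept for local φ refinement

    _ffts: np.ndarray | None = field(default=None, repr=False)
    _fine_cache: dict = field(default_factory=dict, repr=False)

    @property
    def phi_period(self) -> float:
        n1, n2, scale = self.key
        return _entry_phi_period(self.order, scale)


@dataclass
class ReferenceBank:
    """Reference projections for supervised classification.

    All entries share pixel size, box, band limit, and mask radius.
    """

    entries: dict[tuple[int, int, float], BankEntry]
    render: RenderParams
    mask_radius: float
    lattice: Lattice2D

    def __post_init__(self) -> None:
        if self.mask_radius > self.render.box * self.render.apix / 2.0:
            raise ValueError("mask radius exceeds half the box")

    def keys(self) -> list[tuple[int, int, float]]:
        return sorted(self.entries.keys())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mask(self) -> np.ndarray:
        n = self.render.box
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        r2 = (yy - c) ** 2 + (xx - c) ** 2
        return (r2 * self.render.apix ** 2) <= self.mask_radius ** 2


def _entry_phi_period(order: int, scale: float) -> float:
    if scale == 1.0:
        return 360.0 / order
    return 360.0 / math.gcd(order, 2)


def build_reference_bank(
    unit: AsymmetricUnit,
    lattice: Lattice2D,
    wrappings,
    scales,
    render: RenderParams = RenderParams(),
    grid: SearchGrid = SearchGrid(),
    reference_idx=(14, 14),
    mask_radius: float | None = None,
) -> ReferenceBank:
    """Build the projection bank for all (wrapping, scale) combinations.

    Tube models are long enough to fill the mask at the largest searched
    shift; projections are taken at ψ = 0 over each entry's φ period and
    band-limited to ``render.resolution``.
    """
    wrappings = list(wrappings)
    scales = [float(s) for s in scales]
    if not wrappings or not scales:
        raise ValueError("need at least one wrapping and one scale")
    half_extent = render.box * render.apix * (0.5 + grid.shift_max_frac) + 40.0
    if mask_radius is None:
        r_max = max(
            helix_from_wrapping(lattice, w).radius * max(scales) for w in wrappings
        )
        mask_radius = min(
            r_max + 3.0 * render.blob_sigma + 15.0,
            render.box * render.apix / 2.0 - render.apix,
        )
    entries: dict[tuple[int, int, float], BankEntry] = {}
    for w in wrappings:
        sym = helix_from_wrapping(lattice, w)
        round_tube = build_tube(unit, lattice, w, -half_extent, half_extent, reference_idx)
        for scale in scales:
            tube = flatten(round_tube, scale)
            period = _entry_phi_period(sym.order, scale)
            n_phi = max(1, int(round(period / grid.phi_step)))
            phis = np.arange(n_phi) * period / n_phi
            projs = np.empty((n_phi, render.box, render.box), dtype=np.float32)
            for i, phi in enumerate(phis):
                im = project(tube, (phi, 0.0, 0.0, 0.0), render.apix, render.box,
                             render.blob_sigma)
                projs[i] = band_limit(im, render.resolution).data
            key = (sym.index.n1, sym.index.n2, scale)
            entries[key] = BankEntry(key, projs, phis, sym.order, sym.radius,
                                     tube=tube)
    return ReferenceBank(entries, render, float(mask_radius), lattice)


# ---------------------------------------------------------------------------
# masked normalized cross-correlation machinery


def _prep_entry_ffts(entry: BankEntry, mask: np.ndarray) -> np.ndarray:
    """Cache rFFTs of the masked, zero-mean, unit-norm reference projections."""
    if entry._ffts is None:
        n_m = mask.sum()
        refs = entry.projections.astype(np.float64) * mask
        means = refs.sum(axis=(1, 2), keepdims=True) / n_m
        refs = (refs - means) * mask
        norms = np.sqrt((refs ** 2).sum(axis=(1, 2), keepdims=True))
        norms[norms == 0] = 1.0
        refs /= norms
        entry._ffts = sfft.rfft2(refs.astype(np.float32), axes=(1, 2))
    return entry._ffts


def _shift_window(n: int, max_shift: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays selecting circular shifts within ±max_shift."""
    shifts = np.r_[np.arange(0, max_shift + 1), np.arange(n - max_shift, n)]
    signed = np.where(shifts <= max_shift, shifts, shifts - n)
    return shifts, signed


def _seg_denominator(seg_rot, mask_fft, n_mask, rows, cols):
    """Local standard deviation of the segment under every mask shift."""
    n = seg_rot.shape[0]
    seg_fft = sfft.rfft2(seg_rot)
    seg2_fft = sfft.rfft2(seg_rot ** 2)
    d1 = sfft.irfft2(np.conj(mask_fft) * seg_fft, s=(n, n))
    d2 = sfft.irfft2(np.conj(mask_fft) * seg2_fft, s=(n, n))
    var = d2 - d1 ** 2 / n_mask
    denom = np.sqrt(np.maximum(var, 1e-12))
    return seg_fft, denom[np.ix_(rows, cols)]


def _score_maps_max(seg_fft, denom_win, ref_ffts, max_shift):
    """Max masked NCC over the shift window for each reference projection.

    The circular-correlation map is scanned only inside the shift window,
    i.e. its four corners (non-negative and negative shifts along each
    axis).  Returns (best scores, best (dy, dx) window index) per
    projection; indices address the window in ``_shift_window`` order.
    """
    n = seg_fft.shape[0]
    m = max_shift
    num = sfft.irfft2(np.conj(ref_ffts) * seg_fft[None], s=(n, n), axes=(1, 2))
    npr = len(ref_ffts)
    best_scores = np.full(npr, -np.inf, dtype=np.float64)
    best_ij = np.zeros((npr, 2), dtype=int)
    blocks = (
        (slice(0, m + 1), slice(0, m + 1), 0, 0),
        (slice(0, m + 1), slice(n - m, n), 0, m + 1),
        (slice(n - m, n), slice(0, m + 1), m + 1, 0),
        (slice(n - m, n), slice(n - m, n), m + 1, m + 1),
    )
    for rs, cs, r0, c0 in blocks:
        sc = num[:, rs, cs] / denom_win[rs.start and slice(m + 1, None) or slice(0, m + 1),
                                        cs.start and slice(m + 1, None) or slice(0, m + 1)][None]
        flat = sc.reshape(npr, -1)
        kmax = np.argmax(flat, axis=1)
        vals = flat[np.arange(npr), kmax]
        upd = vals > best_scores
        if np.any(upd):
            ii, jj = np.unravel_index(kmax[upd], sc.shape[1:])
            best_scores[upd] = vals[upd]
            best_ij[upd, 0] = ii + r0
            best_ij[upd, 1] = jj + c0
    return best_scores, best_ij


def align_and_score(
    segment: Image,
    entry: BankEntry,
    bank: ReferenceBank,
    grid: SearchGrid = SearchGrid(),
) -> tuple[float, dict]:
    """Globally align a segment to one bank entry.

    Returns (best score, pose) where pose holds φ, ψ (degrees) and the
    integer-pixel shifts (dx, dy) mapping the reference onto the segment.
    Score is the masked normalized cross-correlation, in [-1, 1].
    """
    if segment.box != bank.render.box or segment.apix != bank.render.apix:
        raise ValueError("segment and bank must share box and pixel size")
    mask = bank.mask
    n = segment.box
    max_shift = int(grid.shift_max_frac * n)
    shifts, signed = _shift_window(n, max_shift)
    mask_fft = sfft.rfft2(mask.astype(np.float32))
    n_mask = float(mask.sum())
    ref_ffts = _prep_entry_ffts(entry, mask)

    best = (-np.inf, None)
    for psi in grid.psi_values():
        seg_rot = _rotate_image(segment.data, -psi)
        seg_fft, denom_win = _seg_denominator(seg_rot, mask_fft, n_mask, shifts, shifts)
        scores, ijs = _score_maps_max(seg_fft, denom_win, ref_ffts, max_shift)
        k = int(np.argmax(scores))
        if scores[k] > best[0]:
            dy, dx = signed[ijs[k][0]], signed[ijs[k][1]]
            best = (float(scores[k]), {
                "phi": float(entry.phis[k]), "psi": float(psi),
                "dx": int(dx), "dy": int(dy),
            })
    return best


def _rotate_image(data: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg % 360.0 == 0.0:
        return data.astype(np.float32)
    return ndimage.rotate(data.astype(np.float32), angle_deg, reshape=False, order=1)


def _fine_phi_ffts(entry: BankEntry, bank: ReferenceBank, mask: np.ndarray,
                   phi_indices, refine_factor: int) -> np.ndarray:
    """Masked-normalized rFFTs of projections on the fine φ grid.

    The fine grid subdivides the entry's coarse φ grid ``refine_factor``
    times; projections are rendered lazily from the entry's tube model and
    cached on the entry, so repeated refinements across a stack reuse them.
    Coarse grid points reuse the already-rendered bank projections.
    """
    from .imaging import Image

    n_fine = len(entry.phis) * refine_factor
    period = entry.phi_period
    out = []
    n_m = mask.sum()
    for qi in phi_indices:
        qi = qi % n_fine
        if qi in entry._fine_cache:
            out.append(entry._fine_cache[qi])
            continue
        if qi % refine_factor == 0:
            proj = entry.projections[qi // refine_factor]
        else:
            phi = qi * period / n_fine
            im = project(entry.tube, (phi, 0.0, 0.0, 0.0), bank.render.apix,
                         bank.render.box, bank.render.blob_sigma)
            proj = band_limit(im, bank.render.resolution).data
        ref = proj.astype(np.float64) * mask
        ref = (ref - ref.sum() / n_m) * mask
        nrm = np.sqrt((ref ** 2).sum())
        ref /= nrm if nrm else 1.0
        fft = sfft.rfft2(ref.astype(np.float32))
        entry._fine_cache[qi] = fft
        out.append(fft)
    return np.stack(out)


def classify(
    stack: ImageStack,
    bank: ReferenceBank,
    grid: SearchGrid = SearchGrid(),
    refine_top_k: int = 4,
    refine_factor: int = 3,
) -> pd.DataFrame:
    """Assign every segment to its best-scoring bank entry.

    A coarse pass scores every entry over the full search grid; the
    ``refine_top_k`` best entries are then re-scored on a local φ/ψ grid
    subdivided ``refine_factor`` times around each entry's coarse optimum
    (``refine_top_k=0`` disables refinement).  Returns the assignment table
    with one row per segment: best (n1, n2, scale), score, pose, and the
    margin to the runner-up entry.  Exact score ties are broken toward the
    lowest key in sorted order (and logged).
    """
    if len(stack) == 0 or len(bank) == 0:
        raise ValueError("need a non-empty stack and bank")
    mask = bank.mask
    n = bank.render.box
    max_shift = int(grid.shift_max_frac * n)
    shifts, signed = _shift_window(n, max_shift)
    mask_fft = sfft.rfft2(mask.astype(np.float32))
    n_mask = float(mask.sum())
    keys = bank.keys()
    entry_ffts = {k: _prep_entry_ffts(bank.entries[k], mask) for k in keys}

    rows = []
    for si, seg in enumerate(stack.images):
        # --- coarse pass: best (score, pose) per entry ---------------------
        per_key: dict[tuple, tuple[float, tuple]] = {}
        for psi in grid.psi_values():
            seg_rot = _rotate_image(seg.data, -psi)
            seg_fft, denom_win = _seg_denominator(seg_rot, mask_fft, n_mask,
                                                  shifts, shifts)
            for key in keys:
                entry = bank.entries[key]
                scores, ijs = _score_maps_max(seg_fft, denom_win,
                                              entry_ffts[key], max_shift)
                k = int(np.argmax(scores))
                sc = float(scores[k])
                if key not in per_key or sc > per_key[key][0]:
                    per_key[key] = (sc, (int(k), float(psi),
                                         int(signed[ijs[k][1]]),
                                         int(signed[ijs[k][0]])))
        # coarse poses: φ stored as the coarse grid index, resolve to degrees
        resolved = {
            key: (sc, (float(bank.entries[key].phis[k0]), psi0, dx0, dy0))
            for key, (sc, (k0, psi0, dx0, dy0)) in per_key.items()
        }
        ranked = sorted(per_key.items(), key=lambda kv: (-kv[1][0], kv[0]))

        # --- local refinement of the leading entries -----------------------
        if refine_top_k > 0 and refine_factor > 1:
            psi_fine = np.arange(-(refine_factor - 1), refine_factor) \
                * grid.psi_step / refine_factor
            for key, (sc0, (k0, psi0, dx0, dy0)) in ranked[:refine_top_k]:
                entry = bank.entries[key]
                qs = [k0 * refine_factor + j
                      for j in range(-(refine_factor - 1), refine_factor)]
                ffts = _fine_phi_ffts(entry, bank, mask, qs, refine_factor)
                n_fine = len(entry.phis) * refine_factor
                for dpsi in psi_fine:
                    psi = psi0 + dpsi
                    seg_rot = _rotate_image(seg.data, -psi)
                    seg_fft, denom_win = _seg_denominator(
                        seg_rot, mask_fft, n_mask, shifts, shifts)
                    scores, ijs = _score_maps_max(seg_fft, denom_win, ffts,
                                                  max_shift)
                    k = int(np.argmax(scores))
                    if scores[k] > resolved[key][0]:
                        phi = (qs[k] % n_fine) * entry.phi_period / n_fine
                        resolved[key] = (float(scores[k]),
                                         (phi, float(psi),
                                          int(signed[ijs[k][1]]),
                                          int(signed[ijs[k][0]])))

        order = sorted(resolved.items(), key=lambda kv: (-kv[1][0], kv[0]))
        best_key, (best_score, best_pose) = order[0]
        if len(order) > 1:
            second = order[1][1][0]
            if second == best_score:
                logger.warning(
                    "segment %d: exact score tie between %s and %s; "
                    "keeping the lower key", si, best_key, order[1][0])
        else:
            second = np.nan
        rows.append({
            "segment": si,
            "n1": best_key[0], "n2": best_key[1], "scale": best_key[2],
            "score": best_score,
            "phi": best_pose[0], "psi": best_pose[1],
            "dx": best_pose[2], "dy": best_pose[3],
            "margin": best_score - second,
        })
    return pd.DataFrame(rows)


@dataclass
class Summary:
    """Lattice and flattening histograms of an assignment table."""

    lattice_counts: pd.DataFrame
    flattening: dict[tuple[int, int], pd.DataFrame]

    def to_tsv(self, lattice_path, flattening_path) -> None:
        self.lattice_counts.to_csv(lattice_path, sep="\t", index=False)
        frames = []
        for (n1, n2), df in sorted(self.flattening.items()):
            d = df.copy()
            d.insert(0, "n1", n1)
            d.insert(1, "n2", n2)
            frames.append(d)
        pd.concat(frames).to_csv(flattening_path, sep="\t", index=False)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nsub = 1 + len(self.flattening)
        fig, axes = plt.subplots(1, nsub, figsize=(4 * nsub, 3.2), squeeze=False)
        ax = axes[0][0]
        labels = [f"({r.n1},{r.n2})" for r in self.lattice_counts.itertuples()]
        ax.bar(labels, self.lattice_counts["fraction"])
        ax.set_ylabel("fraction of segments")
        ax.set_title("lattice (n1, n2)")
        ax.tick_params(axis="x", rotation=60)
        for i, ((n1, n2), df) in enumerate(sorted(self.flattening.items()), start=1):
            ax = axes[0][i]
            ax.bar([f"{s:.2f}" for s in df["scale"]], df["fraction"])
            ax.set_title(f"flattening | ({n1},{n2})")
            ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def summarize(table: pd.DataFrame) -> Summary:
    """Histogram the assignments by lattice index and flattening scale.

    Returns per-(n1, n2) counts and fractions (summing to 1), plus, within
    each lattice class, the distribution over flattening scales.
    """
    if len(table) == 0:
        raise ValueError("empty assignment table")
    total = len(table)
    lat = (
        table.groupby(["n1", "n2"]).size().rename("count").reset_index()
        .sort_values(["n1", "n2"], ignore_index=True)
    )
    lat["fraction"] = lat["count"] / total
    flattening = {}
    for (n1, n2), sub in table.groupby(["n1", "n2"]):
        f = sub.groupby("scale").size().rename("count").reset_index()
        f["fraction"] = f["count"] / len(sub)
        flattening[(int(n1), int(n2))] = f
    return Summary(lat, flattening)
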