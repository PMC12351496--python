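"""Synthetic phantoms and count data with exact ground truth.

Every generator is a pure function of its parameters and a seed, and returns
the data container alongside a truth record describing the noise-free
phantom exactly. The generators emulate the study's raw inputs: tube-like
neurite z-stacks with a controllable number of separated fragments,
puncta/marker fields with known coverage, calcium movies with known cell
positions, event trains and kinetics, negative-binomial count matrices with
planted fold changes and stable housekeeping genes, and qPCR Ct tables.

SNR is defined throughout as (peak signal − background) / noise SD and is
recorded in every truth record.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from organoid_quant.calcium_activity import kernel_peak_factor
from organoid_quant.core_io import (
    CountMatrix,
    CtTable,
    Image2D,
    ImageStack3D,
    Movie,
    ValidationError,
    write_json,
)

TRUTH_SCHEMA_VERSION = 1


@dataclass
class PhantomTruth:
    """Exact description of a noise-free imaging phantom."""

    kind: str  # "tubes", "puncta", "bars", or "coloc"
    n_objects: int = 0
    lengths_um: list[float] = field(default_factory=list)
    coverage_fraction: float = 0.0
    coverage_fraction_b: float = 0.0
    overlap_fraction: float = 0.0
    snr: float = float("inf")
    seed: int = 0
    schema_version: int = TRUTH_SCHEMA_VERSION


@dataclass
class CalciumTruth:
    """Planted parameters of a synthetic calcium movie."""

    centers: list[tuple[int, int]]
    event_times_s: list[list[float]]
    event_amplitudes: list[list[float]]
    tau_r_s: float
    tau_d_s: float
    rate_per_min: float
    shared_event_fraction: float
    duration_s: float
    frame_rate_hz: float
    snr: float
    seed: int
    schema_version: int = TRUTH_SCHEMA_VERSION


@dataclass
class CountTruth:
    """Planted structure of a synthetic count matrix."""

    de_genes: list[str]
    true_fold_change: dict[str, float]
    housekeeping_genes: list[str]
    dispersion: float
    library_size_factors: dict[str, float]
    seed: int
    schema_version: int = TRUTH_SCHEMA_VERSION


_TRUTH_REQUIRED = {
    PhantomTruth: {"kind", "snr", "seed", "schema_version"},
    CalciumTruth: {"centers", "event_times_s", "tau_r_s", "tau_d_s", "schema_version"},
    CountTruth: {"de_genes", "true_fold_change", "housekeeping_genes", "schema_version"},
}


def write_truth(path: str | Path, truth) -> None:
    """Serialize a truth record to JSON, validating its schema first."""
    required = _TRUTH_REQUIRED.get(type(truth))
    if required is None:
        raise ValidationError(f"unknown truth type {type(truth).__name__}")
    payload = asdict(truth)
    missing = required - payload.keys()
    if missing:
        raise ValidationError(f"truth record missing fields: {sorted(missing)}")
    write_json(path, payload)


# ---------------------------------------------------------------------------
# 3D tube phantoms


def _random_curve(
    rng: np.random.Generator,
    extent_um: np.ndarray,
    length_um: float,
    margin_um: float,
    step_um: float = 0.2,
    wiggle: float = 0.08,
    z_damp: float = 0.25,
) -> np.ndarray | None:
    """A smooth random 3D polyline of the requested length, inside margins.

    The curve starts at a uniform position, heads in a random mostly
    in-plane direction, and perturbs its direction slowly (no kinks, as a
    neurite bends gently). Returns (n, 3) points in µm (z, y, x), or None
    when the curve would leave the margins (caller retries).
    """
    lo = np.array([margin_um] * 3)
    hi = extent_um - margin_um
    lo[0] = min(lo[0], extent_um[0] * 0.3)
    hi[0] = max(hi[0], extent_um[0] * 0.7)
    pos = rng.uniform(lo, hi)
    d = rng.normal(size=3)
    d[0] *= z_damp
    d /= np.linalg.norm(d)
    n_steps = max(2, int(round(length_um / step_um)))
    pts = [pos.copy()]
    for _ in range(n_steps):
        d = d + wiggle * rng.normal(size=3) * np.array([z_damp, 1.0, 1.0])
        d /= np.linalg.norm(d)
        pos = pos + step_um * d
        if np.any(pos < lo) or np.any(pos > hi):
            return None
        pts.append(pos.copy())
    return np.array(pts)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _rasterize_tube(
    points_um: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    radius_um: float,
) -> np.ndarray:
    """Binary tube mask: all voxels within ``radius_um`` of the polyline.

    The Euclidean distance transform runs on a bounding box around the
    polyline only, which keeps placement fast in large volumes.
    """
    vs = np.asarray(voxel_size_um)
    idx = np.rint(points_um / vs).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    pad = np.ceil(radius_um / vs).astype(int) + 1
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, np.array(shape))
    box_shape = tuple(hi - lo)
    center = np.zeros(box_shape, dtype=bool)
    local = idx - lo
    center[local[:, 0], local[:, 1], local[:, 2]] = True
    dist = ndi.distance_transform_edt(~center, sampling=vs)
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist <= radius_um
    return mask


def gen_tube_phantom(
    n_fragments: int,
    length_range_um: tuple[float, float] = (4.0, 10.0),
    tube_radius_um: float = 0.8,
    volume_shape: tuple[int, int, int] = (32, 512, 512),
    voxel_size_um: tuple[float, float, float] = (0.2, 0.133, 0.133),
    snr: float = 10.0,
    min_separation_um: float = 6.0,
    psf_sigma_px: float = 1.0,
    seed: int = 0,
    max_retries: int = 500,
) -> tuple[ImageStack3D, PhantomTruth]:
    """Generate a z-stack of separated tube-like neurite fragments.

    Fragments are smooth random curves dilated to tubes of
    ``tube_radius_um``, placed by rejection sampling so that tube surfaces
    stay at least ``min_separation_um`` apart (an error is raised if
    placement fails after ``max_retries`` attempts per fragment). The
    noise-free phantom is blurred with a Gaussian PSF and Gaussian noise is
    added at the stated SNR; ``snr=inf`` keeps it noise-free. The truth
    records the exact centerline length of every fragment.
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size_um)
    extent_um = np.array(volume_shape) * vs
    margin_um = tube_radius_um + 2 * psf_sigma_px * vs[2] + 0.5

    signal = np.zeros(volume_shape, dtype=np.float32)
    forbidden = np.zeros(volume_shape, dtype=bool)
    lengths: list[float] = []
    for _ in range(n_fragments):
        placed = False
        for _attempt in range(max_retries):
            length = rng.uniform(*length_range_um)
            curve = _random_curve(rng, extent_um, length, margin_um)
            if curve is None:
                continue
            tube = _rasterize_tube(curve, volume_shape, voxel_size_um, tube_radius_um)
            if not (tube & forbidden).any():
                signal[tube] = 1.0
                halo = _rasterize_tube(
                    curve, volume_shape, voxel_size_um, tube_radius_um + min_separation_um
                )
                forbidden |= halo
                lengths.append(_polyline_length(curve))
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"could not place fragment {len(lengths) + 1}/{n_fragments} "
                f"without overlap after {max_retries} retries"
            )

    blurred = ndi.gaussian_filter(signal, sigma=psf_sigma_px)
    peak = float(blurred.max()) if n_fragments else 1.0
    if np.isfinite(snr) and n_fragments:
        noise_sd = peak / snr
        blurred = blurred + rng.normal(0.0, noise_sd, size=blurred.shape).astype(np.float32)
    blurred = np.clip(blurred, 0.0, None)
    vmax = float(blurred.max())
    if vmax > 0:
        blurred = blurred / vmax
    truth = PhantomTruth(
        kind="tubes",
        n_objects=n_fragments,
        lengths_um=lengths,
        snr=float(snr),
        seed=seed,
    )
    return ImageStack3D(blurred.astype(np.float64), voxel_size_um=tuple(vs)), truth


# ---------------------------------------------------------------------------
# 2D puncta / bar phantoms


def _disk_patch(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def _bar_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    length_px: float,
    width_px: float,
    angle_rad: float,
) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    along = dx * np.cos(angle_rad) + dy * np.sin(angle_rad)
    across = -dx * np.sin(angle_rad) + dy * np.cos(angle_rad)
    return (np.abs(along) <= length_px / 2) & (np.abs(across) <= width_px / 2)


def gen_puncta_image(
    n_objects: int | None = None,
    coverage_target: float | None = 0.12,
    radius_range_px: tuple[int, int] = (3, 7),
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.065,
    mode: str = "spots",
    bar_length_range_um: tuple[float, float] = (0.8, 2.0),
    bar_width_px: float = 3.0,
    background: float = 0.1,
    foreground: float = 0.8,
    snr: float = 8.0,
    seed: int = 0,
) -> tuple[Image2D, PhantomTruth, np.ndarray]:
    """Generate a 2D marker field of puncta (disks) or bar-shaped objects.

    Objects are placed without touching (one-pixel clearance); placement
    stops when ``coverage_target`` is reached or ``n_objects`` are placed,
    whichever is specified. Coverage targets above 0.5 are rejected as
    unrealistically dense. Returns the noisy image, the truth (exact mask
    coverage, object count and lengths), and the noise-free object mask.
    """
    if coverage_target is not None and coverage_target > 0.5:
        raise ValidationError("coverage_target > 0.5 is unrealistically dense")
    if n_objects is None and coverage_target is None:
        raise ValidationError("specify n_objects or coverage_target")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    dilated = np.zeros(shape, dtype=bool)
    lengths_um: list[float] = []
    placed = 0
    attempts = 0
    max_attempts = 20000
    while attempts < max_attempts:
        attempts += 1
        if n_objects is not None and placed >= n_objects:
            break
        if coverage_target is not None and n_objects is None and mask.mean() >= coverage_target:
            break
        if mode == "spots":
            r = int(rng.integers(radius_range_px[0], radius_range_px[1] + 1))
            y = int(rng.integers(r + 1, shape[0] - r - 1))
            x = int(rng.integers(r + 1, shape[1] - r - 1))
            obj = np.zeros(shape, dtype=bool)
            obj[y - r : y + r + 1, x - r : x + r + 1] = _disk_patch(r)
            length_um = (2 * r + 1) * pixel_size_um
        elif mode == "bars":
            length_um = float(rng.uniform(*bar_length_range_um))
            length_px = length_um / pixel_size_um
            ang = float(rng.uniform(0, np.pi))
            pad = length_px / 2 + bar_width_px
            y = float(rng.uniform(pad, shape[0] - pad))
            x = float(rng.uniform(pad, shape[1] - pad))
            obj = _bar_mask(shape, (y, x), length_px, bar_width_px, ang)
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        grown = ndi.binary_dilation(obj, iterations=2)
        if (grown & dilated).any():
            continue
        mask |= obj
        dilated |= grown
        lengths_um.append(length_um)
        placed += 1
    else:
        raise ValidationError("could not place the requested objects without overlap")

    img = np.where(mask, foreground, background).astype(np.float64)
    img = ndi.gaussian_filter(img, sigma=1.0)
    if np.isfinite(snr):
        noise_sd = (foreground - background) / snr
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    truth = PhantomTruth(
        kind=mode,
        n_objects=placed,
        lengths_um=lengths_um,
        coverage_fraction=float(mask.mean()),
        snr=float(snr),
        seed=seed,
    )
    return Image2D(img, pixel_size_um=pixel_size_um), truth, mask


def gen_coloc_pair(
    n_objects: int = 40,
    overlap_fraction: float = 0.3,
    radius_px: int = 4,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.065,
    background: float = 0.1,
    foreground: float = 0.8,
    snr: float = 8.0,
    seed: int = 0,
) -> tuple[Image2D, Image2D, PhantomTruth]:
    """Generate a two-channel field with a planted mask-overlap fraction.

    Channel A holds ``n_objects`` disks; for a ``overlap_fraction`` subset
    of them channel B gets a disk at the same center (full overlap), and the
    remaining B disks are placed disjointly from A. The truth records the
    exact overlap area as a fraction of the field of view and of mask A.
    """
    rng = np.random.default_rng(seed)
    mask_a = np.zeros(shape, dtype=bool)
    mask_b = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    n_shared = int(round(overlap_fraction * n_objects))
    centers: list[tuple[int, int]] = []
    patch = _disk_patch(radius_px)
    r = radius_px

    def place_disjoint() -> tuple[int, int]:
        for _ in range(10000):
            y = int(rng.integers(r + 1, shape[0] - r - 1))
            x = int(rng.integers(r + 1, shape[1] - r - 1))
            obj = np.zeros(shape, dtype=bool)
            obj[y - r : y + r + 1, x - r : x + r + 1] = patch
            if not (ndi.binary_dilation(obj, iterations=2) & occupied).any():
                return y, x
        raise ValidationError("could not place disjoint objects")

    for _ in range(n_objects):
        y, x = place_disjoint()
        mask_a[y - r : y + r + 1, x - r : x + r + 1] |= patch
        occupied |= ndi.binary_dilation(mask_a, iterations=2)
        centers.append((y, x))
    for y, x in centers[:n_shared]:
        mask_b[y - r : y + r + 1, x - r : x + r + 1] |= patch
    for _ in range(n_objects - n_shared):
        y, x = place_disjoint()
        mask_b[y - r : y + r + 1, x - r : x + r + 1] |= patch
        occupied |= ndi.binary_dilation(mask_b, iterations=2)

    def render(mask: np.ndarray) -> Image2D:
        img = np.where(mask, foreground, background).astype(np.float64)
        img = ndi.gaussian_filter(img, sigma=1.0)
        if np.isfinite(snr):
            img = img + rng.normal(0.0, (foreground - background) / snr, size=shape)
        return Image2D(np.clip(img, 0.0, 1.0), pixel_size_um=pixel_size_um)

    overlap = mask_a & mask_b
    truth = PhantomTruth(
        kind="coloc",
        n_objects=n_objects,
        coverage_fraction=float(mask_a.mean()),
        coverage_fraction_b=float(mask_b.mean()),
        overlap_fraction=float(overlap.mean()),
        snr=float(snr),
        seed=seed,
    )
    return render(mask_a), render(mask_b), truth


# ---------------------------------------------------------------------------
# calcium movies


def gen_calcium_movie(
    n_cells: int = 20,
    rate_per_min: float = 1.0,
    tau_r_s: float = 0.5,
    tau_d_s: float = 2.0,
    amp_mean: float = 0.2,
    amp_sd: float = 0.04,
    shared_event_fraction: float = 0.0,
    drift: float = 0.0,
    snr: float = 5.0,
    duration_s: float = 300.0,
    rate_hz: float = 4.0,
    shape: tuple[int, int] = (128, 128),
    cell_sigma_px: float = 3.0,
    min_separation_px: int = 14,
    baseline: float = 0.1,
    cell_brightness: float = 0.5,
    seed: int = 0,
) -> tuple[Movie, CalciumTruth]:
    """Render a synthetic calcium movie with known cells, events and kinetics.

    Cells are Gaussian profiles at positions with a minimum pairwise
    separation. Each cell fires a Poisson event train at ``rate_per_min``;
    a ``shared_event_fraction`` of its events is drawn from one network-wide
    shared train (1.0 makes all cells fire together, giving synchrony 1).
    Each event adds the rise × decay kernel scaled so its ΔF/F₀ *peak*
    equals the drawn amplitude. ``drift`` applies a linear multiplicative
    bleach of that total fraction over the movie. Noise SD is
    (peak transient increment at a cell center) / SNR.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * rate_hz))
    if n_frames < 2:
        raise ValidationError("movie too short")

    centers: list[tuple[int, int]] = []
    pad = int(3 * cell_sigma_px) + 2
    for _ in range(n_cells):
        for _attempt in range(5000):
            y = int(rng.integers(pad, shape[0] - pad))
            x = int(rng.integers(pad, shape[1] - pad))
            if all(
                (y - cy) ** 2 + (x - cx) ** 2 >= min_separation_px**2 for cy, cx in centers
            ):
                centers.append((y, x))
                break
        else:
            raise ValidationError("could not place cells with the requested separation")

    # event trains: shared network train + independent per-cell trains
    t_lo, t_hi = 5.0, duration_s - 4 * tau_d_s
    window = max(t_hi - t_lo, 1.0)

    def poisson_train(rate: float) -> np.ndarray:
        n = rng.poisson(rate / 60.0 * window)
        return np.sort(rng.uniform(t_lo, t_hi, size=n))

    shared = poisson_train(rate_per_min)
    event_times: list[list[float]] = []
    event_amps: list[list[float]] = []
    for _ in range(n_cells):
        own = poisson_train(rate_per_min * (1.0 - shared_event_fraction))
        take = shared[rng.uniform(size=len(shared)) < shared_event_fraction]
        times = np.sort(np.concatenate([own, take]))
        amps = np.maximum(rng.normal(amp_mean, amp_sd, size=len(times)), 0.25 * amp_mean)
        event_times.append([float(t) for t in times])
        event_amps.append([float(a) for a in amps])

    # render
    tgrid = np.arange(n_frames) / rate_hz
    peak_factor = kernel_peak_factor(tau_r_s, tau_d_s)
    movie = np.full((n_frames, *shape), baseline, dtype=np.float32)
    half = pad
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    profile = np.exp(-(yy**2 + xx**2) / (2 * cell_sigma_px**2)).astype(np.float32)
    for (cy, cx), times, amps in zip(centers, event_times, event_amps):
        dff = np.zeros(n_frames, dtype=np.float64)
        for t0, a in zip(times, amps):
            dt = tgrid - t0
            on = dt >= 0
            dff[on] += (
                a / peak_factor * (1.0 - np.exp(-dt[on] / tau_r_s)) * np.exp(-dt[on] / tau_d_s)
            )
        fluor = cell_brightness * (1.0 + dff)
        patch = profile[None, :, :] * fluor[:, None, None].astype(np.float32)
        movie[:, cy - half : cy + half + 1, cx - half : cx + half + 1] += patch
    if drift > 0:
        movie *= (1.0 - drift * tgrid / duration_s)[:, None, None].astype(np.float32)
    if np.isfinite(snr):
        noise_sd = cell_brightness * amp_mean / snr
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape).astype(np.float32)
    movie = np.clip(movie, 0.0, None)

    truth = CalciumTruth(
        centers=centers,
        event_times_s=event_times,
        event_amplitudes=event_amps,
        tau_r_s=tau_r_s,
        tau_d_s=tau_d_s,
        rate_per_min=rate_per_min,
        shared_event_fraction=shared_event_fraction,
        duration_s=duration_s,
        frame_rate_hz=rate_hz,
        snr=float(snr),
        seed=seed,
    )
    return Movie(movie.astype(np.float64), frame_rate_hz=rate_hz), truth


# ---------------------------------------------------------------------------
# count matrices and Ct tables


def gen_count_matrix(
    n_genes: int = 760,
    n_hk: int = 10,
    n_per_group: int = 4,
    de_fraction: float = 0.0,
    fold_change: float = 3.0,
    dispersion: float = 0.1,
    library_size_sd: float = 0.2,
    distribution: str = "negative_binomial",
    log_noise_sd: float = 0.25,
    group_names: tuple[str, str] = ("CTRL", "MUT"),
    seed: int = 0,
) -> tuple[CountMatrix, CountTruth]:
    """Count matrix with planted DE genes and stable housekeeping genes.

    ``n_genes`` endogenous genes plus ``n_hk`` high-abundance housekeeping
    genes; sample-specific library-size factors (log-normal,
    ``library_size_sd``) make normalization non-trivial. A ``de_fraction``
    of the endogenous genes receives a multiplicative fold change in the
    second group (half up at ``fold_change``, half down at its reciprocal).
    Housekeeping genes are never differentially expressed.

    ``distribution`` selects the count model: ``negative_binomial``
    (overdispersed counts, ``dispersion``) emulates nCounter data;
    ``lognormal`` draws exactly normal log-counts with SD ``log_noise_sd``,
    the regime where per-gene t-tests on the log scale are exactly
    calibrated — use it for null-calibration studies.
    """
    if not 0.0 <= de_fraction < 1.0:
        raise ValidationError("de_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    hk_ids = [f"HK{i:02d}" for i in range(n_hk)]
    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    base_hk = rng.uniform(700.0, 2500.0, size=n_hk)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    fc = np.ones(n_genes)
    half = n_de // 2
    fc[de_idx[:half]] = fold_change
    fc[de_idx[half:]] = 1.0 / fold_change

    samples = [f"{g}_{i + 1}" for g in group_names for i in range(n_per_group)]
    groups = {s: (group_names[0] if i < n_per_group else group_names[1]) for i, s in enumerate(samples)}
    lib = rng.lognormal(mean=0.0, sigma=library_size_sd, size=len(samples))

    if distribution not in ("negative_binomial", "lognormal"):
        raise ValidationError(f"unknown distribution {distribution!r}")
    r = 1.0 / dispersion
    counts = np.empty((n_genes + n_hk, len(samples)))
    means_all = np.concatenate([base, base_hk])
    fc_all = np.concatenate([fc, np.ones(n_hk)])
    for j, s in enumerate(samples):
        m = means_all * lib[j]
        if groups[s] == group_names[1]:
            m = m * fc_all
        if distribution == "negative_binomial":
            p = r / (r + m)
            counts[:, j] = rng.negative_binomial(r, p)
        else:
            counts[:, j] = np.exp(np.log(m) + rng.normal(0.0, log_noise_sd, size=len(m)))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids + hk_ids, columns=samples),
        group_of_sample=groups,
        housekeeping_ids=hk_ids,
    )
    truth = CountTruth(
        de_genes=[gene_ids[i] for i in de_idx],
        true_fold_change={gene_ids[i]: float(fc[i]) for i in de_idx},
        housekeeping_genes=hk_ids,
        dispersion=dispersion,
        library_size_factors={s: float(l) for s, l in zip(samples, lib)},
        seed=seed,
    )
    return cm, truth


def gen_ct_table(
    true_rel_expr: dict[str, float],
    ct_noise_sd: float = 0.0,
    n_samples: int = 3,
    ref_gene: str = "ATP5O",
    ct_ref: float = 20.0,
    seed: int = 0,
) -> tuple[CtTable, dict[str, float]]:
    """qPCR Ct table consistent with the given true relative expressions.

    For each sample, Ct_ref is drawn around ``ct_ref`` and each gene's Ct is
    ``Ct_ref − log2(rel_expr)`` plus Gaussian technical noise of
    ``ct_noise_sd`` cycles. With zero noise, 2^−ΔCt recovers the truth
    exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        sample = f"S{i + 1}"
        ctr = ct_ref + rng.normal(0.0, ct_noise_sd)
        rows.append({"sample_label": sample, "gene_id": ref_gene, "ct_value": ctr})
        for gene, rel in true_rel_expr.items():
            ct_g = ctr - np.log2(rel) + rng.normal(0.0, ct_noise_sd)
            rows.append({"sample_label": sample, "gene_id": gene, "ct_value": ct_g})
    return CtTable(pd.DataFrame(rows)), dict(true_rel_expr)
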