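"""Count-recovery and signal-to-noise evaluation on simulated scans.

Two study designs are reproduced in silico:

* a count-recovery sweep — cuvettes seeded with 0 to 20 nematodes, scanned
  with 1 mm sheets at 125 um steps (64 frames per position, 80 positions)
  and counted by the full detection pipeline; recovery is summarized by an
  ordinary least-squares regression of detected on inserted counts plus a
  Spearman rank correlation;
* a brightfield-versus-GD contrast comparison — matched transects through a
  nematode in a raw speckle frame and in the GD activity map of the same
  scene, summarized as the per-scene fold change of the transect S/N.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biospeckle import SNResult, extract_transect, generalized_differences, signal_to_noise
from .detect import DetectionParams, detect_nematodes
from .simulate import (
    AcquisitionConfig,
    ClutterSpec,
    GridGeometry,
    make_scene,
    simulate_scan,
)

__all__ = [
    "CUVETTE_GEOMETRY",
    "EXPERIMENT_ACQ",
    "DEFAULT_COUNTS",
    "RegressionSummary",
    "SNPair",
    "SNFoldSummary",
    "run_recovery_experiment",
    "summarize_recovery",
    "sn_fold_change",
    "run_sn_experiment",
    "plot_recovery",
]

log = logging.getLogger(__name__)

# A 1 cm^2 fluorimeter cuvette cross-section mapped onto a 256 px frame,
# scanned over its full 1 cm depth in 125 um steps (80 positions).
CUVETTE_GEOMETRY = GridGeometry(grid_shape=(256, 256, 80), voxel_size_xy=10000.0 / 256, z_step=125.0)

# Fast automated-detection protocol: thick overlapping sheets.
EXPERIMENT_ACQ = AcquisitionConfig(
    frames_per_position=64,
    frame_rate_hz=10.0,
    n_positions=80,
    z_increment_um=125.0,
    sheet_thickness_um=1000.0,
)

# Six insertion levels spanning the 0-20 animals-per-cuvette range.
DEFAULT_COUNTS: Tuple[int, ...] = (0, 4, 8, 12, 16, 20)


@dataclass
class RegressionSummary:
    r_squared: float
    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class SNPair:
    """Matched transect S/N of a brightfield frame and its GD image."""

    brightfield: SNResult
    gd: SNResult


@dataclass
class SNFoldSummary:
    folds: List[float]
    mean: float
    se: float
    min: float
    max: float
    n_pairs: int
    n_excluded: int


def run_recovery_experiment(
    counts: Sequence[int] = DEFAULT_COUNTS,
    replicates: int = 3,
    medium: str = "clean",
    seed: int = 0,
    geometry: Optional[GridGeometry] = None,
    acq: Optional[AcquisitionConfig] = None,
    params: Optional[DetectionParams] = None,
    alive_fraction: float = 1.0,
) -> pd.DataFrame:
    """Simulate and count one scan per (inserted count, replicate).

    ``medium`` selects the background heterogeneity ("clean" colloid or
    "soil" with strong static refractive-index clutter).  Returns a table
    with columns ``true_count, detected_count, replicate, seed``; fully
    deterministic in ``seed``.
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    geometry = geometry or CUVETTE_GEOMETRY
    acq = acq or EXPERIMENT_ACQ
    rng = np.random.default_rng(seed)
    rows = []
    for count in counts:
        for rep in range(replicates):
            scan_seed = int(rng.integers(0, 2**31 - 1))
            scene = make_scene(
                int(count),
                alive_fraction=alive_fraction,
                geometry=geometry,
                seed=scan_seed,
                medium=medium,
            )
            scan = simulate_scan(scene, acq)
            det = detect_nematodes(scan, params=params)
            rows.append(
                {
                    "true_count": int(count),
                    "detected_count": det.count,
                    "replicate": rep,
                    "seed": scan_seed,
                }
            )
            log.info(
                "recovery %s medium: inserted=%d rep=%d detected=%d",
                medium,
                count,
                rep,
                det.count,
            )
    return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value of the Spearman correlation."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    target = abs(rho_obs) - 1e-12
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = float((rx[list(perm)] * ry).sum()) / denom
        total += 1
        if abs(r) >= target:
            hits += 1
    return hits / total


def summarize_recovery(
    table: pd.DataFrame,
    on: str = "rows",
    through_origin: bool = False,
) -> RegressionSummary:
    """OLS of detected on inserted counts plus Spearman rank correlation.

    ``on="rows"`` regresses every replicate; ``on="means"`` first averages
    detected counts per insertion level (the convention of a means-with-
    error-bars recovery plot).  The Spearman p-value is an exact permutation
    value for n <= 10 points and the usual t approximation otherwise.
    """
    if on == "means":
        g = table.groupby("true_count", as_index=False)["detected_count"].mean()
        x = g["true_count"].to_numpy(dtype=float)
        y = g["detected_count"].to_numpy(dtype=float)
    elif on == "rows":
        x = table["true_count"].to_numpy(dtype=float)
        y = table["detected_count"].to_numpy(dtype=float)
    else:
        raise ValueError("on must be 'rows' or 'means'")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct true_count values")

    if through_origin:
        slope = float((x * y).sum() / (x * x).sum())
        intercept = 0.0
        resid = y - slope * x
        sstot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else 0.0
        r2 = min(max(r2, 0.0), 1.0)
    elif np.std(y) == 0:
        slope, intercept, r2 = 0.0, float(y.mean()), 0.0
    else:
        res = sps.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)

    if np.std(y) == 0:
        rho, p = float("nan"), float("nan")
    else:
        rho = float(sps.spearmanr(x, y).statistic)
        if len(x) <= 10:
            p = _spearman_exact_p(x, y, rho)
        else:
            p = float(sps.spearmanr(x, y).pvalue)
    return RegressionSummary(
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        spearman_rho=rho,
        spearman_p=p,
        n_points=len(x),
    )


def sn_fold_change(pairs: Iterable[SNPair | Tuple[SNResult, SNResult]]) -> SNFoldSummary:
    """Per-pair fold change ``SN_GD / SN_brightfield`` with summary stats.

    Pairs with non-positive brightfield S/N are excluded (the fold is
    undefined) and logged.  An empty input returns an empty summary.
    """
    folds: List[float] = []
    n_excluded = 0
    for pair in pairs:
        if isinstance(pair, tuple):
            pair = SNPair(*pair)
        if pair.brightfield.sn <= 0:
            n_excluded += 1
            log.warning(
                "excluding S/N pair with non-positive brightfield SN=%.3f", pair.brightfield.sn
            )
            continue
        folds.append(pair.gd.sn / pair.brightfield.sn)
    if not folds:
        return SNFoldSummary(
            folds=[], mean=float("nan"), se=float("nan"), min=float("nan"), max=float("nan"),
            n_pairs=0, n_excluded=n_excluded,
        )
    arr = np.asarray(folds)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return SNFoldSummary(
        folds=folds,
        mean=float(arr.mean()),
        se=se,
        min=float(arr.min()),
        max=float(arr.max()),
        n_pairs=arr.size,
        n_excluded=n_excluded,
    )


def run_sn_experiment(
    n_scenes: int = 8,
    seed: int = 0,
    image_px: int = 256,
    pixel_size_um: float = 39.0625,
    clutter_sd_range: Tuple[float, float] = (0.3, 1.2),
) -> Tuple[List[SNPair], pd.DataFrame]:
    """Matched brightfield/GD transect S/N over scenes of varying clutter.

    Each scene holds a single live nematode in a statically cluttered
    medium (the clutter level sweeps ``clutter_sd_range`` across scenes) and
    is imaged at one sheet position.  The same full-width transect through
    the animal's centroid is read from a raw mid-stack frame and from the GD
    map, and S/N is computed with the object window excluded from the
    background statistics (the MRI-style noise convention; including a
    bright object would bound SN by sqrt(n) and understate GD contrast).
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    geometry = GridGeometry(grid_shape=(image_px, image_px, 1), voxel_size_xy=pixel_size_um)
    acq = AcquisitionConfig(n_positions=1)
    rng = np.random.default_rng(seed)
    levels = np.linspace(*clutter_sd_range, n_scenes)
    pairs: List[SNPair] = []
    records = []
    for i, level in enumerate(levels):
        scene_seed = int(rng.integers(0, 2**31 - 1))
        clutter = ClutterSpec(amplitude_sd=float(level), n_bright_grains=20 + 5 * i)
        scene = make_scene(
            1,
            geometry=geometry,
            seed=scene_seed,
            clutter=clutter,
            z_margin_um=0.0,
        )
        scan = simulate_scan(scene, acq)
        stack = scan.stacks[0]
        nem = scene.nematodes[0]
        raw = stack.frames[stack.n_frames // 2]
        gd = generalized_differences(stack).values
        row = int(round(nem.centroid_um[1] / pixel_size_um))
        col = int(round(nem.centroid_um[0] / pixel_size_um))
        row = int(np.clip(row, 0, image_px - 1))
        halfwidth = int(math.ceil(nem.length_um / 2.0 / pixel_size_um)) + 3
        t_raw = extract_transect(raw, (row, 0), (row, image_px - 1), (row, col))
        t_gd = extract_transect(gd, (row, 0), (row, image_px - 1), (row, col))
        # the object's signal is its brightest profile sample, as an operator
        # reading the line profile would report it
        for t in (t_raw, t_gd):
            lo = max(t.signal_index - halfwidth, 0)
            hi = min(t.signal_index + halfwidth + 1, t.samples.size)
            t.signal_index = lo + int(np.argmax(t.samples[lo:hi]))
        sn_bf = signal_to_noise(t_raw, exclude_halfwidth=halfwidth)
        sn_gd = signal_to_noise(t_gd, exclude_halfwidth=halfwidth)
        pairs.append(SNPair(brightfield=sn_bf, gd=sn_gd))
        records.append(
            {
                "scene": i,
                "seed": scene_seed,
                "clutter_sd": float(level),
                "sn_brightfield": sn_bf.sn,
                "sn_gd": sn_gd.sn,
                "fold": sn_gd.sn / sn_bf.sn if sn_bf.sn > 0 else float("nan"),
            }
        )
    return pairs, pd.DataFrame(records)


def plot_recovery(table: pd.DataFrame, path: str, summary: Optional[RegressionSummary] = None):
    """Scatter of mean detected vs inserted counts with SD error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = table.groupby("true_count")["detected_count"]
    x = np.array(sorted(g.groups))
    mean = g.mean().loc[x].to_numpy()
    sd = g.std(ddof=1).fillna(0.0).loc[x].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, mean, yerr=sd, fmt="ko", capsize=3, label="detected (mean ± SD)")
    if summary is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, summary.intercept + summary.slope * xs, "k--", lw=1,
                label=f"OLS: $R^2$ = {summary.r_squared:.4f}")
    ax.plot(x, x, color="0.7", lw=1, label="identity")
    ax.set_xlabel("nematodes inserted")
    ax.set_ylabel("nematodes detected")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
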