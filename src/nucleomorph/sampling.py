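"""Emulators of the two manual nucleus-sampling protocols.

The gold-standard protocol overlays a 5 x 6 grid on the ROI and annotates
complete grid fields, starting from the image center and meandering
outward, until at least 100 nuclei are collected; nuclei touching grid
lines are included, nuclei cut off at the outer image border are not.  The
practicable protocol selects just 12 nuclei per case by stratified
sampling: 4 each with small, intermediate and large area.

Human raters do not sample uniformly; they tend to oversample large,
conspicuous nuclei.  :func:`simulate_rater_measurement` models that with an
area-weighted selection tilt plus multiplicative measurement noise, which
drives the reproducibility experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from nucleomorph.core_io import LabelMask
from nucleomorph.morphometry import NucleusFeatures

__all__ = [
    "GridSpec",
    "StratifiedSpec",
    "RaterBias",
    "GridSample",
    "grid_sample",
    "stratified_sample_12",
    "simulate_rater_measurement",
]


@dataclass(frozen=True)
class GridSpec:
    """5 x 6 grid overlay and the target number of nuclei."""

    rows: int = 5
    cols: int = 6
    target_n: int = 100

    def __post_init__(self) -> None:
        if self.rows * self.cols != 30:
            raise ValueError("the grid protocol uses a 5 x 6 = 30-field grid")

    def field_order(self) -> list[tuple[int, int]]:
        """Deterministic center-out meander over the grid fields.

        Fields are grouped into rings by Chebyshev distance from the grid
        center (for the even number of columns, distance to the nearer of
        the two middle columns); within a ring, rows are visited top to
        bottom with the column direction alternating per row (serpentine).
        The two central fields come first, the outer ring last.
        """
        r_mid = (self.rows - 1) // 2
        c_lo, c_hi = self.cols // 2 - 1, self.cols // 2
        def ring(r: int, c: int) -> int:
            dc = 0 if c_lo <= c <= c_hi else min(abs(c - c_lo), abs(c - c_hi))
            return max(abs(r - r_mid), dc)

        order: list[tuple[int, int]] = []
        max_ring = max(ring(r, c) for r in range(self.rows) for c in range(self.cols))
        for k in range(max_ring + 1):
            fields = [
                (r, c)
                for r in range(self.rows)
                for c in range(self.cols)
                if ring(r, c) == k
            ]
            by_row: dict[int, list[int]] = {}
            for r, c in fields:
                by_row.setdefault(r, []).append(c)
            for i, r in enumerate(sorted(by_row)):
                cols = sorted(by_row[r], reverse=bool(i % 2))
                order.extend((r, c) for c in cols)
        return order


@dataclass(frozen=True)
class StratifiedSpec:
    """12-nucleus stratified selection: 4 per area tercile."""

    n_total: int = 12
    strata: int = 3
    per_stratum: int = 4

    def __post_init__(self) -> None:
        if self.strata * self.per_stratum != self.n_total:
            raise ValueError("strata * per_stratum must equal n_total")


@dataclass(frozen=True)
class RaterBias:
    """Noise model for a simulated human rater.

    ``area_noise_sd`` — SD of multiplicative (lognormal) area measurement
    noise, as a fraction (0.1 = 10% boundary-tracing error).
    ``oversampling_tilt`` — strength of the preference for larger nuclei
    within each stratum (0 = uniform choice).
    """

    area_noise_sd: float = 0.0
    oversampling_tilt: float = 0.0


@dataclass
class GridSample:
    ids: list[int]
    n_sampled: int
    fields_used: int
    shortfall: bool = False


def grid_sample(mask: LabelMask, spec: GridSpec | None = None) -> GridSample:
    """Replay the >=100-nucleus grid protocol on a label mask.

    Grid fields are visited in the documented center-out meander; every
    instance whose pixel set intersects the current field is included
    (touching a grid line is fine), instances touching the outer image
    border are excluded; instances spanning several fields are counted
    once.  Collection stops after the first field that brings the total to
    ``target_n`` or more.  If the whole image holds fewer than ``target_n``
    eligible nuclei, all are returned with ``shortfall=True``.
    """
    spec = spec or GridSpec()
    labels = mask.labels
    h, w = labels.shape
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    excluded = set(int(b) for b in border if b > 0)

    row_edges = np.linspace(0, h, spec.rows + 1).round().astype(int)
    col_edges = np.linspace(0, w, spec.cols + 1).round().astype(int)

    collected: list[int] = []
    seen: set[int] = set()
    fields_used = 0
    for r, c in spec.field_order():
        fields_used += 1
        sub = labels[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]]
        for lab in np.unique(sub):
            lab = int(lab)
            if lab == 0 or lab in seen or lab in excluded:
                continue
            seen.add(lab)
            collected.append(lab)
        if len(collected) >= spec.target_n:
            return GridSample(collected, len(collected), fields_used)
    return GridSample(collected, len(collected), fields_used, shortfall=True)


def _terciles(features: Sequence[NucleusFeatures]) -> list[list[NucleusFeatures]]:
    # sort by (area, id) so ties break deterministically by instance id
    ordered = sorted(
        features, key=lambda f: (f.area, f.id if f.id is not None else 0)
    )
    n = len(ordered)
    lo, hi = n // 3, (2 * n) // 3
    return [list(ordered[:lo]), list(ordered[lo:hi]), list(ordered[hi:])]


def stratified_sample_12(
    features: Sequence[NucleusFeatures],
    spec: StratifiedSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[NucleusFeatures], dict[str, float]]:
    """Select 12 nuclei: 4 from each area tercile, uniformly at random.

    Returns the selection and its summary (mean, SD, max of area), the
    three statistics the practicable protocol reports.  With fewer than 12
    nuclei available, all are taken and the summary flags the shortfall.
    """
    spec = spec or StratifiedSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    features = list(features)
    if len(features) <= spec.n_total:
        chosen = features
        shortfall = len(features) < spec.n_total
    else:
        chosen = []
        for stratum in _terciles(features):
            take = min(spec.per_stratum, len(stratum))
            idx = rng.choice(len(stratum), size=take, replace=False)
            chosen.extend(stratum[i] for i in sorted(idx))
        shortfall = len(chosen) < spec.n_total
    areas = np.array([f.area for f in chosen])
    summary = {
        "n": float(len(chosen)),
        "area_mean": float(areas.mean()),
        "area_sd": float(np.std(areas, ddof=1)) if areas.size >= 2 else float("nan"),
        "area_max": float(areas.max()),
        "shortfall": float(shortfall),
    }
    return chosen, summary


def simulate_rater_measurement(
    features: Sequence[NucleusFeatures],
    bias: RaterBias | None = None,
    seed: int | np.random.Generator = 0,
    spec: StratifiedSpec | None = None,
) -> dict[str, float]:
    """One simulated pathologist performing the 12-nucleus measurement.

    Within each tercile the selection probability is proportional to
    ``area ** oversampling_tilt`` (tilt 0 = the unbiased protocol); each
    selected area is then multiplied by lognormal noise with the given
    fractional SD.  Deterministic per seed.
    """
    bias = bias or RaterBias()
    spec = spec or StratifiedSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    features = list(features)
    if len(features) <= spec.n_total:
        chosen = features
    else:
        chosen = []
        for stratum in _terciles(features):
            areas = np.array([f.area for f in stratum])
            if bias.oversampling_tilt:
                w = areas**bias.oversampling_tilt
                p = w / w.sum()
            else:
                p = None
            take = min(spec.per_stratum, len(stratum))
            idx = rng.choice(len(stratum), size=take, replace=False, p=p)
            chosen.extend(stratum[i] for i in sorted(idx))
    areas = np.array([f.area for f in chosen], dtype=float)
    if bias.area_noise_sd > 0:
        areas = areas * np.exp(rng.normal(0.0, bias.area_noise_sd, size=areas.size))
    return {
        "n": float(areas.size),
        "area_mean": float(areas.mean()),
        "area_sd": float(np.std(areas, ddof=1)) if areas.size >= 2 else float("nan"),
        "area_max": float(areas.max()),
    }
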