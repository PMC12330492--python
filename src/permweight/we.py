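"""Weighted-ensemble protocol on the permeant z progress coordinate.

Implements the standard WE machinery: binning of walkers on z, split/merge
resampling to a per-bin target count, dynamic bin insertion at the
membrane–extracellular interface, steady-state recycling at the outer
boundaries, lineage tracking for the macrostate flux, and an HDF5 run
store.

Geometry convention: z is measured from the bilayer center, positive on
the extracellular side.  Macrostates are extracellular (z > 20 Å), bilayer
(|z| < 20 Å) and intracellular (z < −20 Å); recycling replaces walkers at
z > 55 Å or z < −25 Å with fresh source walkers of identical weight, so
the sink flux yields steady-state kinetics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import ConfigError, OverflowBinWarning, WeightConservationError
from .landscape import (
    ToyLandscape,
    Walker,
    _step_batch,
    check_time_step,
    sample_observables,
)
from .titration import neutral_fraction

__all__ = [
    "LINEAGE_LABELS",
    "BinScheme",
    "WalkerTable",
    "IterationRecord",
    "build_bin_scheme",
    "assign",
    "resample",
    "recycle",
    "run_weighted_ensemble",
    "save_run",
    "load_run",
]

#: Integer codes used for lineage labels in walker tables.
LINEAGE_LABELS = ("none", "extracellular", "intracellular")
_LIN_NONE, _LIN_EXT, _LIN_INT = 0, 1, 2
# titration lineage codes: outside bilayer / (bilayer, protonated) / (bilayer, deprotonated)
_TIT_NONE, _TIT_PROT, _TIT_DEPROT = 0, 1, 2


@dataclass
class BinScheme:
    """Ordered z bin boundaries with environment-dependent spacing."""

    boundaries: np.ndarray
    solvent_spacing: float = 5.0
    membrane_spacing: float = 0.5
    membrane_extent: float = 20.0
    dynamic_region: tuple[float, float] = (20.0, 25.0)
    target_count: int = 4

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ConfigError("bin boundaries must be strictly increasing")
        if self.target_count < 1:
            raise ConfigError("target_count must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.boundaries.size - 1

    def copy(self) -> "BinScheme":
        return replace(self, boundaries=self.boundaries.copy())


def build_bin_scheme(
    solvent_spacing: float = 5.0,
    membrane_spacing: float = 0.5,
    membrane_extent: float = 20.0,
    lower_bound: float = -25.0,
    upper_bound: float = 55.0,
    dynamic_region: tuple[float, float] = (20.0, 25.0),
    target_count: int = 4,
    prefill_dynamic: bool = False,
) -> BinScheme:
    """Construct the documented bin layout.

    The membrane interval [−membrane_extent, membrane_extent] is tiled at
    ``membrane_spacing`` (0.5 Å default → 80 membrane bins); the solvent is
    tiled at ``solvent_spacing`` out to the recycle boundaries.  With the
    defaults this yields 88 bins; the exact count is reported, not asserted,
    because the construction is configurable.  ``prefill_dynamic`` also
    tiles the dynamic region (the membrane–extracellular interface) at
    membrane spacing from the start — the protocol variant used to enhance
    sampling of membrane-partitioning events.
    """
    if not (lower_bound < -membrane_extent < membrane_extent < upper_bound):
        raise ConfigError("recycle bounds must bracket the membrane extent")
    if solvent_spacing <= 0 or membrane_spacing <= 0:
        raise ConfigError("bin spacings must be positive")
    m = membrane_extent
    n_mem = int(round(2 * m / membrane_spacing))
    parts = [np.linspace(-m, m, n_mem + 1)]
    # lower solvent: -membrane_extent down to lower_bound
    lo = np.arange(-m - solvent_spacing, lower_bound - 1e-9, -solvent_spacing)
    if lo.size == 0 or lo[-1] > lower_bound + 1e-9:
        lo = np.append(lo, lower_bound)
    parts.append(lo)
    # upper solvent: membrane_extent up to upper_bound
    hi = np.arange(m + solvent_spacing, upper_bound + 1e-9, solvent_spacing)
    if hi.size == 0 or hi[-1] < upper_bound - 1e-9:
        hi = np.append(hi, upper_bound)
    parts.append(hi)
    if prefill_dynamic:
        parts.append(
            np.arange(dynamic_region[0], dynamic_region[1] + 1e-9, membrane_spacing)
        )
    boundaries = np.unique(np.round(np.concatenate(parts), 9))
    return BinScheme(
        boundaries=boundaries,
        solvent_spacing=solvent_spacing,
        membrane_spacing=membrane_spacing,
        membrane_extent=membrane_extent,
        dynamic_region=dynamic_region,
        target_count=target_count,
    )


@dataclass
class WalkerTable:
    """Column-oriented container for a set of weighted walkers."""

    z: np.ndarray
    lam: np.ndarray
    weight: np.ndarray
    lineage: np.ndarray  # int8 codes into LINEAGE_LABELS
    tit_lineage: np.ndarray  # int8 codes: none / bilayer-protonated / bilayer-deprotonated
    observables: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.lineage = np.asarray(self.lineage, dtype=np.int8)
        self.tit_lineage = np.asarray(self.tit_lineage, dtype=np.int8)
        if np.any(self.weight <= 0):
            raise ValueError("all walker weights must be positive")

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    def take(self, idx: np.ndarray) -> "WalkerTable":
        return WalkerTable(
            z=self.z[idx],
            lam=self.lam[idx],
            weight=self.weight[idx],
            lineage=self.lineage[idx],
            tit_lineage=self.tit_lineage[idx],
            observables={k: v[idx] for k, v in self.observables.items()},
        )

    def copy(self) -> "WalkerTable":
        return self.take(np.arange(self.n))

    def to_walkers(self) -> list[Walker]:
        return [
            Walker(
                z=float(self.z[i]),
                lam=float(self.lam[i]),
                weight=float(self.weight[i]),
                observables={k: float(v[i]) for k, v in self.observables.items()},
                lineage=LINEAGE_LABELS[self.lineage[i]],
                rng_stream_id=i,
            )
            for i in range(self.n)
        ]

    @classmethod
    def from_walkers(cls, walkers: Sequence[Walker]) -> "WalkerTable":
        obs_keys = set()
        for w in walkers:
            obs_keys.update(w.observables)
        return cls(
            z=np.array([w.z for w in walkers], dtype=float),
            lam=np.array([w.lam for w in walkers], dtype=float),
            weight=np.array([w.weight for w in walkers], dtype=float),
            lineage=np.array(
                [LINEAGE_LABELS.index(w.lineage) for w in walkers], dtype=np.int8
            ),
            tit_lineage=np.zeros(len(walkers), dtype=np.int8),
            observables={
                k: np.array([w.observables.get(k, np.nan) for w in walkers])
                for k in sorted(obs_keys)
            },
        )


@dataclass
class IterationRecord:
    """End-of-iteration snapshot plus the per-iteration flux tallies."""

    index: int
    tau: float  # ps
    walkers: WalkerTable
    recycled_weight_upper: float = 0.0
    recycled_weight_lower: float = 0.0
    new_intracellular_weight: float = 0.0
    new_deprotonated_weight: float = 0.0
    n_bins: int = 0


def assign(walkers, scheme: BinScheme) -> np.ndarray:
    """Assign walkers to bins using the half-open convention [b_i, b_{i+1}).

    Accepts a WalkerTable, a list of Walker, or a bare z array.  Walkers
    beyond the outermost boundaries are clamped to the terminal bins with a
    warning.
    """
    if isinstance(walkers, WalkerTable):
        z = walkers.z
    elif isinstance(walkers, (list, tuple)):
        z = np.array([w.z for w in walkers], dtype=float)
    else:
        z = np.asarray(walkers, dtype=float)
    idx = np.searchsorted(scheme.boundaries, z, side="right") - 1
    out_of_range = (idx < 0) | (idx >= scheme.n_bins)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} walker(s) beyond the outermost bin boundary; "
            "assigned to the terminal overflow bin",
            OverflowBinWarning,
            stacklevel=2,
        )
        idx = np.clip(idx, 0, scheme.n_bins - 1)
    return idx


def resample(
    walkers,
    bin_ids: np.ndarray,
    target_count: int,
    rng: np.random.Generator | int,
) -> WalkerTable:
    """Split/merge walkers so every occupied bin holds exactly target_count.

    Splitting replicates the highest-weight walker into two equal-weight
    copies until the count is reached; merging combines the two
    lowest-weight walkers, the survivor chosen with probability
    proportional to weight and absorbing both weights (statistically
    exact).  Per-bin total weight is conserved exactly; empty bins are
    untouched.  Deterministic given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    table = walkers if isinstance(walkers, WalkerTable) else WalkerTable.from_walkers(walkers)
    bin_ids = np.asarray(bin_ids)
    if bin_ids.shape != (table.n,):
        raise ValueError("bin_ids must give one bin index per walker")
    src_idx: list[int] = []
    new_weight: list[float] = []
    for b in np.unique(bin_ids):
        members = np.flatnonzero(bin_ids == b)
        entries = [[float(table.weight[i]), int(i)] for i in members]
        while len(entries) < target_count:
            j = max(range(len(entries)), key=lambda k: entries[k][0])
            w, i = entries[j]
            entries[j] = [w / 2.0, i]
            entries.append([w / 2.0, i])
        while len(entries) > target_count:
            order = sorted(range(len(entries)), key=lambda k: entries[k][0])
            j0, j1 = order[0], order[1]
            w0, i0 = entries[j0]
            w1, i1 = entries[j1]
            survivor = i0 if rng.random() < w0 / (w0 + w1) else i1
            merged = [w0 + w1, survivor]
            for j in sorted((j0, j1), reverse=True):
                entries.pop(j)
            entries.append(merged)
        src_idx.extend(i for _, i in entries)
        new_weight.extend(w for w, _ in entries)
    idx = np.asarray(src_idx, dtype=int)
    out = table.take(idx)
    out.weight = np.asarray(new_weight, dtype=float)
    return out


def recycle(
    walkers: WalkerTable,
    upper_bound: float = 55.0,
    lower_bound: float = -25.0,
    source_z: float = 30.0,
    source_deprot_prob: float = 0.0,
    rng: np.random.Generator | int = 0,
    obs_params=None,
) -> tuple[WalkerTable, float, float]:
    """Replace out-of-bounds walkers by source-state walkers of equal weight.

    Walkers with z > upper_bound or z < lower_bound are re-initialized at
    ``source_z`` with λ drawn from the solution equilibrium
    (``source_deprot_prob``), fresh observables and reset lineage.  Returns
    the updated table and the recycled weight per boundary.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    table = walkers.copy()
    up = table.z > upper_bound
    lo = table.z < lower_bound
    w_up = float(table.weight[up].sum())
    w_lo = float(table.weight[lo].sum())
    out = up | lo
    if np.any(out):
        n_out = int(out.sum())
        table.z[out] = source_z
        table.lam[out] = (rng.random(n_out) < source_deprot_prob).astype(float)
        table.lineage[out] = _LIN_NONE
        table.tit_lineage[out] = _TIT_NONE
        if table.observables:
            fresh = sample_observables(
                table.z[out], table.lam[out], obs_params, rng
            ) if obs_params is not None else None
            for k, v in table.observables.items():
                v[out] = fresh[k] if fresh is not None else np.nan
    return table, w_up, w_lo


def _update_lineages(table: WalkerTable, membrane_extent: float) -> tuple[float, float]:
    """Update macrostate and titration lineages in place.

    Returns (weight newly entering the intracellular macrostate with
    extracellular lineage, weight newly deprotonating inside the bilayer).
    """
    z = table.z
    ext = z > membrane_extent
    intr = z < -membrane_extent
    new_int = intr & (table.lineage == _LIN_EXT)
    flux_weight = float(table.weight[new_int].sum())
    table.lineage[ext] = _LIN_EXT
    table.lineage[intr] = _LIN_INT

    in_bilayer = ~ext & ~intr
    prot = in_bilayer & (table.lam < 0.2)
    deprot = in_bilayer & (table.lam > 0.8)
    new_deprot = deprot & (table.tit_lineage == _TIT_PROT)
    deprot_weight = float(table.weight[new_deprot].sum())
    table.tit_lineage[~in_bilayer] = _TIT_NONE
    table.tit_lineage[prot] = _TIT_PROT
    table.tit_lineage[deprot] = _TIT_DEPROT
    return flux_weight, deprot_weight


def _insert_dynamic_bins(
    scheme: BinScheme, bin_ids: np.ndarray, table: WalkerTable
) -> tuple[BinScheme, np.ndarray, bool]:
    """Split occupied bins inside the dynamic region until none exceeds
    membrane spacing; boundaries are inserted at mid-gap."""
    lo, hi = scheme.dynamic_region
    changed = False
    while True:
        b = scheme.boundaries
        widths = np.diff(b)
        occupied = np.zeros(scheme.n_bins, dtype=bool)
        occupied[np.unique(bin_ids)] = True
        inside = (b[:-1] >= lo - 1e-9) & (b[1:] <= hi + 1e-9)
        split = inside & occupied & (widths > scheme.membrane_spacing * (1 + 1e-9))
        if not np.any(split):
            return scheme, bin_ids, changed
        mids = (b[:-1] + b[1:])[split] / 2.0
        scheme = replace(scheme, boundaries=np.sort(np.concatenate([b, mids])))
        bin_ids = assign(table, scheme)
        changed = True


def run_weighted_ensemble(
    landscape: ToyLandscape,
    scheme: BinScheme | None = None,
    n_iterations: int = 100,
    tau: float = 100.0,
    pH: float = 7.5,
    seed: int = 0,
    dt: float = 10.0,
    source_z: float = 30.0,
    recycle_bounds: tuple[float, float] | None = (-25.0, 55.0),
    init: str = "source",
    dynamic_bins: bool = True,
    store_observables: bool = True,
    z_walls: tuple[float, float] | None = None,
    log: bool = False,
) -> list[IterationRecord]:
    """Run a steady-state (or sink-free) weighted-ensemble simulation.

    Each iteration propagates every walker for ``tau`` ps of coupled
    Brownian/titration dynamics, updates lineages and tallies the
    extracellular→intracellular flux, recycles out-of-bounds walkers (when
    ``recycle_bounds`` is set), assigns walkers to bins (inserting dynamic
    bins at the interface as needed) and resamples each occupied bin to the
    target count.  Fully reproducible from the seed.

    ``init='source'`` starts all weight at the source position;
    ``init='uniform'`` seeds one walker per bin with equal weights
    (useful for sink-free equilibrium runs).  ``z_walls`` places reflecting
    walls; the default extends 5 Å beyond the outer boundaries.
    """
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    if scheme is None:
        scheme = build_bin_scheme()
    scheme = scheme.copy()
    check_time_step(landscape, dt, bin_width=scheme.membrane_spacing)
    rng = np.random.default_rng(seed)
    n_steps = int(round(tau / dt))
    if z_walls is None:
        z_walls = (scheme.boundaries[0] - 5.0, scheme.boundaries[-1] + 5.0)
    f_src = neutral_fraction(landscape.solution_pKa, pH)
    obs_params = landscape.observables

    def _fresh_table(z: np.ndarray, weight: np.ndarray) -> WalkerTable:
        lam = (rng.random(z.size) < f_src).astype(float)
        obs = (
            sample_observables(z, lam, obs_params, rng)
            if store_observables
            else {}
        )
        return WalkerTable(
            z=z,
            lam=lam,
            weight=weight,
            lineage=np.zeros(z.size, dtype=np.int8),
            tit_lineage=np.zeros(z.size, dtype=np.int8),
            observables=obs,
        )

    if init == "source":
        k = scheme.target_count
        table = _fresh_table(np.full(k, float(source_z)), np.full(k, 1.0 / k))
    elif init == "uniform":
        centers = (scheme.boundaries[:-1] + scheme.boundaries[1:]) / 2.0
        table = _fresh_table(centers.copy(), np.full(centers.size, 1.0 / centers.size))
    else:
        raise ConfigError(f"unknown init mode {init!r}")

    records: list[IterationRecord] = []
    for it in range(n_iterations):
        z, lam = _step_batch(
            table.z, table.lam, landscape, pH, dt, n_steps, rng, *z_walls
        )
        table.z, table.lam = z, lam
        if store_observables:
            table.observables = sample_observables(z, lam, obs_params, rng)
        flux_w, deprot_w = _update_lineages(table, scheme.membrane_extent)
        w_up = w_lo = 0.0
        if recycle_bounds is not None:
            table, w_up, w_lo = recycle(
                table,
                upper_bound=recycle_bounds[1],
                lower_bound=recycle_bounds[0],
                source_z=source_z,
                source_deprot_prob=f_src,
                rng=rng,
                obs_params=obs_params if store_observables else None,
            )
        bin_ids = assign(table, scheme)
        if dynamic_bins:
            scheme, bin_ids, _ = _insert_dynamic_bins(scheme, bin_ids, table)
        table = resample(table, bin_ids, scheme.target_count, rng)
        total = table.total_weight
        if abs(total - 1.0) > 1e-9:
            raise WeightConservationError(
                f"total weight {total!r} deviates from 1 at iteration {it}"
            )
        records.append(
            IterationRecord(
                index=it,
                tau=tau,
                walkers=table.copy(),
                recycled_weight_upper=w_up,
                recycled_weight_lower=w_lo,
                new_intracellular_weight=flux_w,
                new_deprotonated_weight=deprot_w,
                n_bins=scheme.n_bins,
            )
        )
        if log:
            print(
                f"iter {it:5d}  walkers {table.n:4d}  bins {scheme.n_bins:3d}  "
                f"flux_w {flux_w:.3e}  total_w {total:.9f}"
            )
    return records


# -- run store ---------------------------------------------------------------


def save_run(records: list[IterationRecord], path: str | Path, config: dict | None = None) -> None:
    """Persist a WE run to HDF5 (one group per iteration + a JSON manifest)."""
    config = dict(config or {})
    manifest = json.dumps(config, sort_keys=True, default=str)
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = manifest
        f.attrs["config_hash"] = hashlib.sha256(manifest.encode()).hexdigest()
        f.attrs["n_iterations"] = len(records)
        for rec in records:
            g = f.create_group(f"iterations/{rec.index:06d}")
            g.attrs.update(
                tau=rec.tau,
                recycled_weight_upper=rec.recycled_weight_upper,
                recycled_weight_lower=rec.recycled_weight_lower,
                new_intracellular_weight=rec.new_intracellular_weight,
                new_deprotonated_weight=rec.new_deprotonated_weight,
                n_bins=rec.n_bins,
            )
            t = rec.walkers
            g.create_dataset("z", data=t.z)
            g.create_dataset("lam", data=t.lam)
            g.create_dataset("weight", data=t.weight)
            g.create_dataset("lineage", data=t.lineage)
            g.create_dataset("tit_lineage", data=t.tit_lineage)
            for k, v in t.observables.items():
                g.create_dataset(f"obs_{k}", data=v)


def load_run(path: str | Path) -> tuple[list[IterationRecord], dict]:
    """Load a WE run saved by :func:`save_run`; returns (records, config)."""
    records = []
    with h5py.File(path, "r") as f:
        config = json.loads(f.attrs["manifest"])
        for name in sorted(f["iterations"]):
            g = f[f"iterations/{name}"]
            obs = {
                k[len("obs_"):]: g[k][...] for k in g if k.startswith("obs_")
            }
            table = WalkerTable(
                z=g["z"][...],
                lam=g["lam"][...],
                weight=g["weight"][...],
                lineage=g["lineage"][...],
                tit_lineage=g["tit_lineage"][...],
                observables=obs,
            )
            records.append(
                IterationRecord(
                    index=int(name),
                    tau=float(g.attrs["tau"]),
                    walkers=table,
                    recycled_weight_upper=float(g.attrs["recycled_weight_upper"]),
                    recycled_weight_lower=float(g.attrs["recycled_weight_lower"]),
                    new_intracellular_weight=float(g.attrs["new_intracellular_weight"]),
                    new_deprotonated_weight=float(g.attrs["new_deprotonated_weight"]),
                    n_bins=int(g.attrs["n_bins"]),
                )
            )
    return records, config
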