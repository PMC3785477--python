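"""Facilitated-diffusion simulation of DNA-binding molecules.

Cognate and non-cognate species share one linear DNA segment under
steric hindrance (no base pair covered twice).  3D diffusion is implicit:
a free molecule binds at rate ``k_assoc`` to a uniformly drawn start; a
bound molecule leaves its position at rate ``1/tau`` and slides, hops or
unbinds.  The heavy lifting is done by the compiled event loop in
:mod:`tfocc._kernel`; this module provides the typed configuration,
result containers and serialization.

All molecules start in the free pool at t = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernel
from .motifs import EnergyLandscape, flat_landscape

DEFAULT_MOVE_PROBS = (0.4, 0.4, 0.1, 0.1)  # left, right, hop, unbind

EVENT_NAMES = ("bind", "bind_blocked", "slide", "slide_rejected",
               "hop", "hop_blocked_to_pool", "hop_rejected_edge", "unbind")


@dataclass
class SpeciesParams:
    """One DNA-binding species.

    landscape=None means a flat (sequence-independent) landscape with
    baseline waiting time ``tau0`` — the non-cognate crowder case.
    """

    name: str
    footprint: int
    abundance: int
    k_assoc: float = 1.0
    landscape: EnergyLandscape | None = None
    tau0: float = 1.0
    move_probs: tuple[float, float, float, float] = DEFAULT_MOVE_PROBS
    hop_range: int = 100

    def __post_init__(self):
        mp = np.asarray(self.move_probs, dtype=float)
        if mp.shape != (4,) or np.any(mp < 0) or abs(mp.sum() - 1.0) > 1e-12:
            raise ValueError("move_probs must be 4 non-negative values summing to 1")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.abundance < 0 or self.k_assoc < 0:
            raise ValueError("abundance and k_assoc must be >= 0")
        if self.hop_range < 1:
            raise ValueError("hop_range must be >= 1")

    def waiting_times(self, dna_length: int) -> np.ndarray:
        """(n_strands, n_starts) mean waiting times on a DNA of given length."""
        n_starts = dna_length - self.footprint + 1
        if n_starts < 1:
            raise ValueError(f"footprint of {self.name} exceeds DNA length")
        if self.landscape is None:
            return np.full((1, n_starts), self.tau0)
        if self.landscape.n_starts != n_starts:
            raise ValueError(
                f"landscape of {self.name} has {self.landscape.n_starts} starts; "
                f"DNA of length {dna_length} with footprint {self.footprint} "
                f"requires {n_starts}")
        return self.landscape.waiting_times.T.copy()


@dataclass
class SimConfig:
    """Full specification of one stochastic simulation."""

    dna_length: int
    species: list[SpeciesParams]
    t_end: float
    seed: int = 0
    snapshot_times: list[float] | None = None

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        max_fp = max((sp.footprint for sp in self.species), default=1)
        if self.dna_length < max_fp:
            raise ValueError("dna_length must be at least the largest footprint")
        demand = sum(sp.abundance * sp.footprint for sp in self.species)
        if demand > self.dna_length:
            warnings.warn(
                f"total footprint demand ({demand} bp) exceeds DNA length "
                f"({self.dna_length} bp); most binding attempts will fail",
                stacklevel=2)

    def species_by_name(self, name: str) -> SpeciesParams:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(f"unknown species {name!r}")


@dataclass
class ResidenceRecord:
    """Bookkeeping of one simulation run.

    residence[name] : (n_strands, n_starts) seconds bound per start position.
    final_positions[name] : encoded end state per molecule
        (strand * n_starts + start, or -1 if free).
    """

    t_sim: float
    dna_length: int
    residence: dict[str, np.ndarray]
    final_positions: dict[str, np.ndarray]
    bound_time: dict[str, np.ndarray]
    free_time: dict[str, np.ndarray]
    event_counts: dict[str, dict[str, int]]
    footprints: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    snapshots: dict | None = None

    def species_names(self) -> list[str]:
        return list(self.residence)

    def to_tsv(self, path) -> None:
        """TSV of (species, position, strand, seconds_bound); zero rows skipped."""
        strands = "+-"
        with open(path, "w") as fh:
            fh.write("species\tposition\tstrand\tseconds_bound\n")
            for name, res in self.residence.items():
                for s in range(res.shape[0]):
                    for p in np.nonzero(res[s])[0]:
                        fh.write(f"{name}\t{p}\t{strands[s]}\t{res[s, p]:.8g}\n")

    def coverage_seconds(self, species: str) -> np.ndarray:
        """Per-bp covered time (start residence expanded over the footprint)."""
        res = self.residence[species].sum(axis=0)
        fp = self.footprints[species]
        # covered[b] = sum of residence over starts p with p <= b < p + fp
        cov = np.convolve(res, np.ones(fp))
        assert cov.size == self.dna_length
        return cov

    def to_bedgraph(self, species: str, path, chrom: str = "seq") -> None:
        from .motifs import write_bedgraph
        write_bedgraph(self.coverage_seconds(species), path, chrom=chrom)


@dataclass
class EnsembleSnapshots:
    """End-of-run molecule states from independent replicate simulations."""

    t_sim: float
    dna_length: int
    positions: dict[str, np.ndarray]   # name -> (n_reps, abundance) encoded states
    footprints: dict[str, int]
    n_replicates: int


def _pack(config: SimConfig):
    """Flatten a SimConfig into the arrays the kernel consumes."""
    n_sp = len(config.species)
    fp = np.empty(n_sp, dtype=np.int64)
    k_assoc = np.empty(n_sp, dtype=np.float64)
    n_starts = np.empty(n_sp, dtype=np.int64)
    n_strands = np.empty(n_sp, dtype=np.int64)
    state_off = np.empty(n_sp, dtype=np.int64)
    hop_range = np.empty(n_sp, dtype=np.int64)
    move_cum = np.empty((n_sp, 4), dtype=np.float64)
    taus = []
    off = 0
    sp_of = []
    for i, sp in enumerate(config.species):
        wt = sp.waiting_times(config.dna_length)
        fp[i] = sp.footprint
        k_assoc[i] = sp.k_assoc
        n_strands[i], n_starts[i] = wt.shape
        state_off[i] = off
        hop_range[i] = sp.hop_range
        move_cum[i] = np.cumsum(sp.move_probs)
        move_cum[i, 3] = 1.0 + 1e-12  # guard against float round-down
        taus.append(wt.ravel())
        off += wt.size
        sp_of.extend([i] * sp.abundance)
    tau_flat = np.concatenate(taus) if taus else np.zeros(0)
    sp_of = np.asarray(sp_of, dtype=np.int64)
    return fp, k_assoc, n_starts, n_strands, state_off, move_cum, hop_range, tau_flat, sp_of


def _buffers(config: SimConfig, n_mol: int):
    bitmap = np.zeros(config.dna_length, dtype=np.uint8)
    state = np.empty(n_mol, dtype=np.int64)
    t_entered = np.empty(n_mol, dtype=np.float64)
    hq_t = np.empty(max(n_mol, 1), dtype=np.float64)
    hq_m = np.empty(max(n_mol, 1), dtype=np.int64)
    return bitmap, state, t_entered, hq_t, hq_m


def simulate(config: SimConfig) -> ResidenceRecord:
    """Run one exact event-driven simulation until ``t_end``."""
    packed = _pack(config)
    fp, k_assoc, n_starts, n_strands, state_off, move_cum, hop_range, tau_flat, sp_of = packed
    n_mol = sp_of.size
    n_sp = len(config.species)

    residence = np.zeros(tau_flat.size, dtype=np.float64)
    final_state = np.full(n_mol, -1, dtype=np.int64)
    bound_time = np.zeros(n_mol, dtype=np.float64)
    free_time = np.zeros(n_mol, dtype=np.float64)
    event_counts = np.zeros((max(n_sp, 1), _kernel.N_EVENT_TYPES), dtype=np.int64)
    snap_times = np.asarray(sorted(config.snapshot_times or []), dtype=np.float64)
    snaps = np.zeros((snap_times.size, n_mol), dtype=np.int64)

    if n_mol > 0:
        bitmap, state, t_entered, hq_t, hq_m = _buffers(config, n_mol)
        _kernel._sim_core(
            int(config.seed), float(config.t_end), int(config.dna_length),
            fp, k_assoc, n_starts, n_strands, state_off, move_cum, hop_range,
            tau_flat, sp_of,
            True, residence,
            final_state, bound_time, free_time, event_counts,
            snap_times, snaps,
            bitmap, state, t_entered, hq_t, hq_m)

    res_d, fin_d, bt_d, ft_d, ev_d, fp_d = {}, {}, {}, {}, {}, {}
    mol_lo = 0
    for i, sp in enumerate(config.species):
        size = int(n_strands[i] * n_starts[i])
        res_d[sp.name] = residence[state_off[i]: state_off[i] + size].reshape(
            int(n_strands[i]), int(n_starts[i]))
        hi = mol_lo + sp.abundance
        fin_d[sp.name] = final_state[mol_lo:hi].copy()
        bt_d[sp.name] = bound_time[mol_lo:hi].copy()
        ft_d[sp.name] = free_time[mol_lo:hi].copy()
        ev_d[sp.name] = {n: int(c) for n, c in zip(EVENT_NAMES, event_counts[i])}
        fp_d[sp.name] = sp.footprint
        mol_lo = hi

    rec = ResidenceRecord(
        t_sim=config.t_end, dna_length=config.dna_length,
        residence=res_d, final_positions=fin_d,
        bound_time=bt_d, free_time=ft_d, event_counts=ev_d,
        footprints=fp_d, seed=config.seed)
    if snap_times.size:
        rec.snapshots = {"times": snap_times, "states": snaps}
    return rec


def simulate_replicates(config: SimConfig, n_replicates: int,
                        base_seed: int) -> list[ResidenceRecord]:
    """Independent replicates with seeds ``base_seed + i``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        cfg = SimConfig(dna_length=config.dna_length, species=config.species,
                        t_end=config.t_end, seed=(base_seed + i) % (2**31 - 1),
                        snapshot_times=config.snapshot_times)
        out.append(simulate(cfg))
    return out


def ensemble_snapshots(config: SimConfig, n_replicates: int,
                       base_seed: int) -> EnsembleSnapshots:
    """End-of-run positions from ``n_replicates`` independent simulations.

    Seeds are ``base_seed + i``; only the final molecule states are
    retained, which keeps very large ensembles cheap.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    packed = _pack(config)
    fp, k_assoc, n_starts, n_strands, state_off, move_cum, hop_range, tau_flat, sp_of = packed
    n_mol = sp_of.size
    finals = np.full((n_replicates, n_mol), -1, dtype=np.int64)
    if n_mol == 1 and k_assoc[sp_of[0]] > 0:
        # single molecule: no steric interactions, use the sequential path
        s = sp_of[0]
        _kernel._ensemble1_core(
            int(base_seed) % (2**31 - 1), int(n_replicates),
            float(config.t_end), float(k_assoc[s]), int(n_starts[s]),
            int(n_strands[s]), move_cum[s], int(hop_range[s]),
            tau_flat[state_off[s]: state_off[s] + n_strands[s] * n_starts[s]],
            finals)
    elif n_mol > 0:
        bitmap, state, t_entered, hq_t, hq_m = _buffers(config, n_mol)
        bound_time = np.zeros(n_mol)
        free_time = np.zeros(n_mol)
        event_counts = np.zeros((len(config.species), _kernel.N_EVENT_TYPES),
                                dtype=np.int64)
        _kernel._ensemble_core(
            int(base_seed) % (2**31 - 1), int(n_replicates),
            float(config.t_end), int(config.dna_length),
            fp, k_assoc, n_starts, n_strands, state_off, move_cum, hop_range,
            tau_flat, sp_of, finals,
            bitmap, state, t_entered, hq_t, hq_m,
            bound_time, free_time, event_counts)

    pos_d, fp_d = {}, {}
    mol_lo = 0
    for sp in config.species:
        hi = mol_lo + sp.abundance
        pos_d[sp.name] = finals[:, mol_lo:hi].copy()
        fp_d[sp.name] = sp.footprint
        mol_lo = hi
    return EnsembleSnapshots(t_sim=config.t_end, dna_length=config.dna_length,
                             positions=pos_d, footprints=fp_d,
                             n_replicates=n_replicates)


def bound_time_fraction(record: ResidenceRecord, species: str) -> float:
    """Mean over molecules of bound_time / t_sim, in [0, 1]."""
    if species not in record.bound_time:
        raise KeyError(f"unknown species {species!r}")
    bt = record.bound_time[species]
    if bt.size == 0:
        return 0.0
    return float(np.mean(bt) / record.t_sim)


# ---------------------------------------------------------------------------
# config file round-trip (YAML key-value schema)


def config_to_dict(config: SimConfig) -> dict:
    return {
        "dna_length": config.dna_length,
        "t_end": config.t_end,
        "seed": config.seed,
        "snapshot_times": list(config.snapshot_times or []),
        "species": [
            {
                "name": sp.name, "footprint": sp.footprint,
                "abundance": sp.abundance, "k_assoc": sp.k_assoc,
                "tau0": sp.tau0, "move_probs": list(sp.move_probs),
                "hop_range": sp.hop_range,
                "landscape": "sequence-specific" if sp.landscape is not None else "flat",
            }
            for sp in config.species
        ],
    }


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path, landscapes: dict[str, EnergyLandscape] | None = None) -> SimConfig:
    """Load a YAML config; sequence-specific species take their landscape
    from the ``landscapes`` mapping by species name."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    species = []
    for sd in d.get("species", []):
        lsc = None
        if sd.get("landscape") == "sequence-specific":
            if not landscapes or sd["name"] not in landscapes:
                raise ValueError(f"species {sd['name']!r} needs a landscape")
            lsc = landscapes[sd["name"]]
        species.append(SpeciesParams(
            name=sd["name"], footprint=int(sd["footprint"]),
            abundance=int(sd["abundance"]), k_assoc=float(sd.get("k_assoc", 1.0)),
            landscape=lsc, tau0=float(sd.get("tau0", 1.0)),
            move_probs=tuple(sd.get("move_probs", DEFAULT_MOVE_PROBS)),
            hop_range=int(sd.get("hop_range", 100))))
    return SimConfig(dna_length=int(d["dna_length"]), species=species,
                     t_end=float(d["t_end"]), seed=int(d.get("seed", 0)),
                     snapshot_times=d.get("snapshot_times") or None)
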