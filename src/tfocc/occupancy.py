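"""Occupancy estimators and affinity-vs-simulation comparison statistics.

Two notions of occupancy are compared per start position:

* **ADO** (affinity-derived occupancy): the equilibrium prediction from
  the binding-energy landscape alone, ``ADO_j = tau_j / sum_i tau_i``
  (strand waiting times summed per start).
* **SDO** (simulation-derived occupancy): measured from stochastic
  simulations, either as a *time* average (accumulated bound seconds of
  one run / t_sim), an *ensemble* average (fraction of independent runs
  whose molecules end at each start — the analogue of a ChIP readout),
  or a *hybrid* average (ensemble mean of per-run time averages), the
  default estimator for all headline analyses here.

Comparison statistics follow the max-normalized linear-ratio convention
(per-site SDO/ADO after dividing each track by its maximum) with t-based
confidence intervals, and natural-log ratios for estimator-vs-estimator
(ergodicity) checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .motifs import EnergyLandscape
from .simulator import EnsembleSnapshots, ResidenceRecord

LOG_ZERO_SENTINEL = -np.inf


@dataclass(frozen=True)
class OccupancyTrack:
    """Per-start occupancy values with estimator metadata."""

    values: np.ndarray
    estimator: str                 # ado | time | ensemble | hybrid
    normalized: str = "none"       # none | sum | max
    n_replicates: int = 1
    t_sim: float = float("nan")

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("occupancy values must be >= 0")
        object.__setattr__(self, "values", v)

    def max_normalized(self) -> np.ndarray:
        vmax = self.values.max()
        if vmax <= 0:
            raise ValueError("cannot max-normalize an all-zero track")
        return self.values / vmax

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tvalue\n")
            for p, v in enumerate(self.values):
                fh.write(f"{p}\t{v:.8g}\n")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-site SDO/ADO ratio statistics over a set of sites."""

    site_positions: np.ndarray
    ado_norm: np.ndarray
    sdo_norm: np.ndarray
    ratios: np.ndarray             # sdo_norm / ado_norm at included sites
    included: np.ndarray           # mask: sites with sdo_norm > 0
    mean_ratio: float
    ci95: tuple[float, float]
    log_ratios: np.ndarray
    t_stat: float
    p_value: float

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    def summary_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mean_ratio\tci_low\tci_high\tt_stat\tp_value\tn_sites\tn_excluded\n")
            fh.write(f"{self.mean_ratio:.6g}\t{self.ci95[0]:.6g}\t{self.ci95[1]:.6g}\t"
                     f"{self.t_stat:.6g}\t{self.p_value:.6g}\t"
                     f"{self.ratios.size}\t{self.n_excluded}\n")

    def per_site_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tado_norm\tsdo_norm\tratio\n")
            for i, p in enumerate(self.site_positions):
                r = (self.sdo_norm[i] / self.ado_norm[i]
                     if self.sdo_norm[i] > 0 else float("nan"))
                fh.write(f"{p}\t{self.ado_norm[i]:.6g}\t{self.sdo_norm[i]:.6g}\t{r:.6g}\n")


# ---------------------------------------------------------------------------
# estimators


def ado(landscape: EnergyLandscape) -> OccupancyTrack:
    """Affinity-derived occupancy: Boltzmann-weighted waiting times.

    Strands are combined by summing the two strand waiting times at each
    start; the track is normalized to sum to 1.
    """
    tau = landscape.waiting_times.sum(axis=1)
    return OccupancyTrack(values=tau / tau.sum(), estimator="ado",
                          normalized="sum")


def sdo_time(record: ResidenceRecord, species: str) -> OccupancyTrack:
    """Time-average occupancy of one run: bound seconds per start / t_sim."""
    if species not in record.residence:
        raise KeyError(f"unknown species {species!r}")
    values = record.residence[species].sum(axis=0) / record.t_sim
    return OccupancyTrack(values=values, estimator="time", t_sim=record.t_sim)


def sdo_ensemble(snapshots: EnsembleSnapshots | list, species: str) -> OccupancyTrack:
    """Ensemble-average occupancy from end-of-run positions.

    The value at each start is the fraction of (replicate, molecule)
    draws that ended bound there — effectively the readout of a ChIP
    experiment over a cell population.
    """
    if isinstance(snapshots, list):
        if not snapshots:
            raise ValueError("empty snapshot list")
        parts = [s.positions[species] for s in snapshots]
        states = np.concatenate(parts, axis=0)
        ref = snapshots[0]
    else:
        states = snapshots.positions[species]
        ref = snapshots
    if species not in ref.positions:
        raise KeyError(f"unknown species {species!r}")
    n_starts = ref.dna_length - ref.footprints[species] + 1
    total = states.size
    counts = np.zeros(n_starts)
    if total:
        bound = states[states >= 0] % n_starts  # strand-summed starts
        np.add.at(counts, bound, 1.0)
        values = counts / total
    else:
        values = counts
    return OccupancyTrack(values=values, estimator="ensemble",
                          n_replicates=states.shape[0] if states.ndim == 2 else 1,
                          t_sim=ref.t_sim)


def sdo_hybrid(records: list[ResidenceRecord], species: str) -> OccupancyTrack:
    """Hybrid average: ensemble mean of per-replicate time averages."""
    if not records:
        raise ValueError("at least one record is required")
    t0 = records[0].t_sim
    if any(abs(r.t_sim - t0) > 1e-9 * max(t0, 1.0) for r in records):
        raise ValueError("all records must share the same t_sim")
    tracks = [sdo_time(r, species).values for r in records]
    return OccupancyTrack(values=np.mean(tracks, axis=0), estimator="hybrid",
                          n_replicates=len(records), t_sim=t0)


# ---------------------------------------------------------------------------
# normalization and site selection


def normalize_log_max(track: OccupancyTrack) -> np.ndarray:
    """ln(values / max): the maximum maps to 0, zeros to -inf (excluded
    from downstream statistics)."""
    norm = track.max_normalized()
    with np.errstate(divide="ignore"):
        return np.where(norm > 0, np.log(norm), LOG_ZERO_SENTINEL)


def select_strong_sites(landscape: EnergyLandscape,
                        fraction_of_max: float = 0.3) -> np.ndarray:
    """Start positions whose (stronger-strand) energy is at least
    ``fraction_of_max`` of the maximum energy."""
    if not 0 < fraction_of_max <= 1:
        raise ValueError("fraction_of_max must be in (0, 1]")
    e = landscape.site_energy()
    return np.nonzero(e >= fraction_of_max * e.max())[0]


def strong_site_percentage(landscape: EnergyLandscape,
                           fraction_of_max: float = 0.3) -> float:
    """Realized percentage of starts selected by the energy threshold."""
    sites = select_strong_sites(landscape, fraction_of_max)
    return 100.0 * sites.size / landscape.n_starts


# ---------------------------------------------------------------------------
# comparison statistics


def _t_ci(x: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    m = float(np.mean(x))
    if x.size < 2:
        return (m, m)
    se = float(stats.sem(x))
    if se == 0:
        return (m, m)
    lo, hi = stats.t.interval(confidence, x.size - 1, loc=m, scale=se)
    return (float(lo), float(hi))


def compare(sdo: OccupancyTrack, ado_track: OccupancyTrack,
            sites: np.ndarray) -> ComparisonResult:
    """Per-site ratio statistics between max-normalized SDO and ADO.

    Sites where the SDO is exactly zero (never visited in finite
    sampling) are excluded from the ratios and counted separately.
    The t-test is a one-sample test of the ln ratios against 0.
    """
    sites = np.asarray(sites, dtype=int)
    if sites.size == 0:
        raise ValueError("sites must be non-empty")
    if sdo.values.shape != ado_track.values.shape:
        raise ValueError("tracks must share coordinates")
    sdo_n = sdo.max_normalized()[sites]
    ado_n = ado_track.max_normalized()[sites]
    included = sdo_n > 0
    if not included.any():
        raise ValueError("no site with non-zero SDO")
    ratios = sdo_n[included] / ado_n[included]
    log_ratios = np.log(ratios)
    mean_ratio = float(np.mean(ratios))
    ci = _t_ci(ratios)
    if ratios.size >= 2 and np.std(log_ratios) > 0:
        t_stat, p_value = stats.ttest_1samp(log_ratios, 0.0)
    else:
        t_stat, p_value = float("nan"), float("nan")
    return ComparisonResult(
        site_positions=sites, ado_norm=ado_n, sdo_norm=sdo_n, ratios=ratios,
        included=included, mean_ratio=mean_ratio, ci95=ci,
        log_ratios=log_ratios, t_stat=float(t_stat), p_value=float(p_value))


def count_exceeding(sdo: OccupancyTrack, ado_track: OccupancyTrack,
                    phi: float, sites=None) -> int:
    """Number of positions where max-normalized SDO/ADO >= phi.

    ``sites=None`` means all positions (no affinity cut-off).  With the
    tracks swapped this counts 'false negative' sites instead.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    sdo_n = sdo.max_normalized()
    ado_n = ado_track.max_normalized()
    if sites is not None:
        sites = np.asarray(sites, dtype=int)
        sdo_n, ado_n = sdo_n[sites], ado_n[sites]
    mask = sdo_n > 0
    with np.errstate(divide="ignore"):
        ratio = np.where(mask & (ado_n > 0), sdo_n / np.where(ado_n > 0, ado_n, 1.0),
                         np.where(mask, np.inf, 0.0))
    return int(np.sum(mask & (ratio >= phi)))


def count_high_occupancy(sdo: OccupancyTrack, threshold: float) -> int:
    """Number of positions with SDO >= threshold * max(SDO)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    vmax = sdo.values.max()
    if vmax <= 0:
        raise ValueError("all-zero track")
    return int(np.sum(sdo.values >= threshold * vmax))


def affinity_band_classification(sites: np.ndarray, landscape: EnergyLandscape,
                                 band_edges: tuple[float, float] = (0.7, 0.3)) -> list[str]:
    """Label each site high / medium / non-specific by energy relative to max.

    ``band_edges = (hi, lo)``: energy >= hi*max -> 'high',
    >= lo*max -> 'medium', below -> 'non-specific'.
    """
    hi, lo = band_edges
    if not hi >= lo:
        raise ValueError("band_edges must be (high, low) with high >= low")
    e = landscape.site_energy()
    emax = e.max()
    labels = []
    for p in np.asarray(sites, dtype=int):
        frac = e[p] / emax if emax > 0 else 0.0
        if frac >= hi:
            labels.append("high")
        elif frac >= lo:
            labels.append("medium")
        else:
            labels.append("non-specific")
    return labels
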