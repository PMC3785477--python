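"""Config-driven experiment grids at desk scale.

The full study sweeps cognate abundance × molecular crowding on a ~100 kb
genomic segment over cell-cycle-length simulations.  Those scales are
reachable through configuration, but the defaults here are sized for a
single workstation CPU: a 10 kb synthetic substrate, shorter model time,
and replicate counts in the tens.  All analyses run the same code paths
regardless of scale.

A *cell* of the grid is one (cognate abundance, crowding coverage) pair;
for each cell the runner produces the hybrid-average SDO, the ADO, their
per-site ratio statistics over strong sites, exceedance counts over a
phi grid, high-occupancy counts, an expected ChIP-like profile, and
absolute (unnormalized) occupancy summaries.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .chip import ProfileConfig, smooth_profile
from .motifs import Motif, energy_from_scores, score_landscape
from .occupancy import (ado, compare, count_exceeding, count_high_occupancy,
                        sdo_ensemble, sdo_hybrid, sdo_time, select_strong_sites,
                        strong_site_percentage)
from .simulator import (DEFAULT_MOVE_PROBS, SimConfig, SpeciesParams,
                        ensemble_snapshots, simulate_replicates)
from .synth import Substrate, crowding_config, make_substrate

COGNATE = "cognate"
NONCOGNATE = "noncognate"


@dataclass
class StudyDesign:
    """Desk-scale study conditions (see docs/methods.md for rationale)."""

    dna_length: int = 10_000
    gc: float = 0.5
    motif_length: int = 21
    motif_ic: float = 19.0          # bits; bacterial-range, high-IC motif
    top_site_energy: float = 5.0    # kBT of the strongest site above baseline
    floor_quantile: float = 0.99
    tau0: float = 1.0               # non-specific waiting time (model seconds)
    cognate_k_assoc: float = 1.0
    move_probs: tuple = DEFAULT_MOVE_PROBS
    hop_range: int = 100
    nc_footprint: int = 50
    nc_tau0: float = 20.0           # slowly exchanging crowders
    nc_k_assoc: float = 0.2
    expected_bound_fraction: float = 0.9
    strong_fraction: float = 0.3    # strong-site energy threshold (of max)
    t_rep: float = 2.0e6            # per-replicate simulation time
    n_reps: int = 20                # hybrid-average replicates
    t_ens: float = 8000.0           # per-snapshot simulation time (ensemble);
                                    # several relaxation times of the slowest
                                    # mode (strongest-site exchange)

    def substrate(self, seed: int) -> Substrate:
        return make_substrate(seed, dna_length=self.dna_length, gc=self.gc,
                              motif_length=self.motif_length,
                              motif_ic=self.motif_ic,
                              top_site_energy=self.top_site_energy,
                              floor_quantile=self.floor_quantile,
                              tau0=self.tau0)

    def species(self, substrate: Substrate, n_cognate: int,
                coverage: float = 0.0,
                motif: Motif | None = None) -> list[SpeciesParams]:
        """Cognate + (optional) non-cognate species for one grid cell.

        Passing a (truncated) motif rescans the substrate with it, using
        the same energy-calibration rule as the full motif.
        """
        if motif is None:
            landscape = substrate.landscape
            footprint = substrate.motif.length
        else:
            track = score_landscape(motif, substrate.sequence, strand_mode="both")
            floor = float(np.quantile(track.scores, self.floor_quantile))
            gap = float(track.scores.max() - floor)
            landscape = energy_from_scores(
                track, scaling=self.top_site_energy / gap,
                floor_quantile=self.floor_quantile, tau0=self.tau0)
            footprint = motif.length
        species = [SpeciesParams(
            name=COGNATE, footprint=footprint, abundance=n_cognate,
            k_assoc=self.cognate_k_assoc, landscape=landscape, tau0=self.tau0,
            move_probs=self.move_probs, hop_range=self.hop_range)]
        if coverage > 0:
            n_nc = crowding_config(coverage, self.nc_footprint,
                                   substrate.dna_length,
                                   self.expected_bound_fraction)
            species.append(SpeciesParams(
                name=NONCOGNATE, footprint=self.nc_footprint, abundance=n_nc,
                k_assoc=self.nc_k_assoc, landscape=None, tau0=self.nc_tau0,
                move_probs=self.move_probs, hop_range=self.hop_range))
        return species

    def cell_config(self, substrate: Substrate, n_cognate: int,
                    coverage: float, t_end: float, seed: int,
                    motif: Motif | None = None) -> SimConfig:
        return SimConfig(dna_length=substrate.dna_length,
                         species=self.species(substrate, n_cognate, coverage,
                                              motif=motif),
                         t_end=t_end, seed=seed)


@dataclass
class CellResult:
    """Hybrid SDO vs ADO for one grid cell."""

    abundance: int
    coverage: float
    sdo: object
    ado: object
    comparison: object
    strong_sites: np.ndarray
    absolute_peak: float          # unnormalized hybrid SDO at the strongest site
    mean_bound_fraction: float
    replicate_mean_ratios: np.ndarray = field(default_factory=lambda: np.zeros(0))


def run_cell(design: StudyDesign, substrate: Substrate, n_cognate: int,
             coverage: float, seed: int, n_reps: int | None = None,
             t_rep: float | None = None) -> CellResult:
    """Simulate one (abundance, crowding) cell and compare SDO with ADO."""
    n_reps = n_reps if n_reps is not None else design.n_reps
    t_rep = t_rep if t_rep is not None else design.t_rep
    cfg = design.cell_config(substrate, n_cognate, coverage, t_rep, seed)
    recs = simulate_replicates(cfg, n_reps, base_seed=seed)
    sdo = sdo_hybrid(recs, COGNATE)
    ado_track = ado(substrate.landscape)
    sites = select_strong_sites(substrate.landscape, design.strong_fraction)
    cmp_res = compare(sdo, ado_track, sites)
    rep_means = []
    for rec in recs:
        track = sdo_time(rec, COGNATE)
        if track.values[sites].max() > 0:
            rep_means.append(compare(track, ado_track, sites).mean_ratio)
    from .simulator import bound_time_fraction
    bf = float(np.mean([bound_time_fraction(r, COGNATE) for r in recs]))
    peak = float(sdo.values[int(np.argmax(substrate.landscape.site_energy()))])
    return CellResult(abundance=n_cognate, coverage=coverage, sdo=sdo,
                      ado=ado_track, comparison=cmp_res, strong_sites=sites,
                      absolute_peak=peak, mean_bound_fraction=bf,
                      replicate_mean_ratios=np.asarray(rep_means))


@dataclass
class GridConfig:
    """What `run_grid` sweeps and where results go."""

    out_dir: str
    seed: int = 1
    abundances: tuple = (1, 10, 100)
    coverages: tuple = (0.0, 0.26)
    phi_grid: tuple = (1.25, 1.5, 2.0, 3.0, 5.0)
    high_occupancy_thresholds: tuple = (0.05, 0.1, 0.2)
    fragment_length: int = 150
    n_reps: int | None = None
    t_rep: float | None = None
    design: StudyDesign = field(default_factory=StudyDesign)


def run_grid(grid: GridConfig) -> Path:
    """Run the abundance × crowding grid; write TSV/bedGraph results.

    Returns the results directory.  Outputs per cell: ratio summary and
    per-site table, exceedance counts over the phi grid (computed over
    all positions, no affinity cut-off), high-occupancy counts, an
    expected ChIP profile, and the absolute occupancy summary.  A
    manifest records the config hash, seeds and package version.
    """
    out = Path(grid.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = grid.design
    substrate = design.substrate(grid.seed)
    substrate.write(out / "substrate.fa", out / "motif.pfm", out / "truth.tsv")

    rows, exceed_rows, high_rows = [], [], []
    for ai, abundance in enumerate(grid.abundances):
        for ci, coverage in enumerate(grid.coverages):
            cell_seed = grid.seed + 100_000 * (ai * len(grid.coverages) + ci + 1)
            res = run_cell(design, substrate, abundance, coverage,
                           seed=cell_seed, n_reps=grid.n_reps, t_rep=grid.t_rep)
            tag = f"a{abundance}_c{int(round(coverage * 100))}"
            res.comparison.summary_tsv(out / f"ratio_summary_{tag}.tsv")
            res.comparison.per_site_tsv(out / f"ratio_sites_{tag}.tsv")
            res.sdo.to_tsv(out / f"sdo_{tag}.tsv")
            profile = smooth_profile(
                res.sdo, ProfileConfig(fragment_length=grid.fragment_length),
                footprint=substrate.motif.length)
            from .motifs import write_bedgraph
            write_bedgraph(profile, out / f"chip_profile_{tag}.bedgraph")
            for phi in grid.phi_grid:
                exceed_rows.append({
                    "abundance": abundance, "coverage": coverage, "phi": phi,
                    "n_exceeding": count_exceeding(res.sdo, res.ado, phi),
                    "n_false_negative": count_exceeding(res.ado, res.sdo, phi)})
            for thr in grid.high_occupancy_thresholds:
                high_rows.append({
                    "abundance": abundance, "coverage": coverage,
                    "threshold": thr,
                    "n_high": count_high_occupancy(res.sdo, thr)})
            rows.append({
                "abundance": abundance, "coverage": coverage,
                "mean_ratio": res.comparison.mean_ratio,
                "ci_low": res.comparison.ci95[0],
                "ci_high": res.comparison.ci95[1],
                "n_strong_sites": res.strong_sites.size,
                "absolute_peak_occupancy": res.absolute_peak,
                "bound_fraction": res.mean_bound_fraction})
    pd.DataFrame(rows).to_csv(out / "grid_summary.tsv", sep="\t", index=False)
    pd.DataFrame(exceed_rows).to_csv(out / "exceedance_counts.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(high_rows).to_csv(out / "high_occupancy_counts.tsv", sep="\t",
                                   index=False)

    cfg_dict = {k: v for k, v in asdict(grid).items()}
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": grid.seed,
        "strong_site_percentage": strong_site_percentage(
            substrate.landscape, design.strong_fraction),
        "package_version": _pkg_version,
        "python": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# ergodicity and convergence reports


def _ln_ratio_stats(a: np.ndarray, b: np.ndarray, sites: np.ndarray):
    """Mean/SD/t-test of ln(a/b) over sites where both are positive."""
    av, bv = a[sites], b[sites]
    ok = (av > 0) & (bv > 0)
    if ok.sum() == 0:
        return np.nan, np.nan, np.nan, 0
    lr = np.log(av[ok] / bv[ok])
    if lr.size >= 2 and np.std(lr) > 0:
        _, p = stats.ttest_1samp(lr, 0.0)
    else:
        p = np.nan
    return float(np.mean(lr)), float(np.std(lr, ddof=1)) if lr.size > 1 else 0.0, \
        float(p), int(lr.size)


def ergodicity_report(design: StudyDesign, substrate: Substrate,
                      n_cognate: int = 1, coverage: float = 0.0,
                      n_replicates: int = 20, t_list=(5e5, 2e6),
                      n_ensemble: int = 50_000, t_ens: float | None = None,
                      seed: int = 1) -> pd.DataFrame:
    """Compare time-, hybrid- and ensemble-average occupancy over strong sites.

    For each simulation time in ``t_list``: runs ``n_replicates``
    replicates, forms per-replicate time averages and their hybrid mean,
    estimates the ensemble average from ``n_ensemble`` independent
    end-of-run snapshots, and reports the mean, SD and one-sample t-test
    p-value of ln(time/ensemble) and ln(hybrid/ensemble) over strong
    sites where both estimates are non-zero.
    """
    if len(t_list) < 1:
        raise ValueError("at least one simulation time is required")
    sites = select_strong_sites(substrate.landscape, design.strong_fraction)
    ens_cfg = design.cell_config(substrate, n_cognate, coverage,
                                 t_ens or design.t_ens, seed)
    snaps = ensemble_snapshots(ens_cfg, n_ensemble, base_seed=seed + 777)
    ens = sdo_ensemble(snaps, COGNATE)

    rows = []
    for ti, t_sim in enumerate(sorted(t_list)):
        cfg = design.cell_config(substrate, n_cognate, coverage, float(t_sim),
                                 seed)
        recs = simulate_replicates(cfg, n_replicates,
                                   base_seed=seed + 10_000 * (ti + 1))
        time_tracks = [sdo_time(r, COGNATE) for r in recs]
        hybrid = sdo_hybrid(recs, COGNATE)
        # time average: the longest single-system view we have is the
        # per-replicate mean of ln ratios (each replicate is one system)
        per_rep = [_ln_ratio_stats(tt.values, ens.values, sites)
                   for tt in time_tracks]
        means = [m for m, *_ in per_rep if np.isfinite(m)]
        time_mean = float(np.mean(means)) if means else np.nan
        time_sd = float(np.std(means, ddof=1)) if len(means) > 1 else np.nan
        if len(means) > 1 and np.std(means) > 0:
            _, time_p = stats.ttest_1samp(means, 0.0)
        else:
            time_p = np.nan
        h_mean, h_sd, h_p, h_n = _ln_ratio_stats(hybrid.values, ens.values, sites)
        rows.append({
            "t_sim": t_sim,
            "mean_ln_time_over_ensemble": time_mean,
            "sd_ln_time_over_ensemble": time_sd,
            "p_ln_time_over_ensemble": float(time_p),
            "mean_ln_hybrid_over_ensemble": h_mean,
            "sd_ln_hybrid_over_ensemble": h_sd,
            "p_ln_hybrid_over_ensemble": h_p,
            "n_sites_used": h_n,
        })
    return pd.DataFrame(rows)


def convergence_report(design: StudyDesign, substrate: Substrate,
                       n_cognate: int = 1, coverage: float = 0.0,
                       t_list=(2.5e5, 5e5, 1e6), n_replicates: int = 10,
                       seed: int = 1, rel_tol: float = 0.1) -> pd.DataFrame:
    """Mean and SD of strong-site occupancy versus simulation time.

    Longer simulations reduce replicate-to-replicate variability while
    the mean occupancy stays put; the report flags the smallest time at
    which successive mean occupancies agree within ``rel_tol``.
    """
    if len(t_list) < 2:
        raise ValueError("at least two time points are required")
    sites = select_strong_sites(substrate.landscape, design.strong_fraction)
    rows = []
    prev_mean = None
    for ti, t_sim in enumerate(sorted(t_list)):
        cfg = design.cell_config(substrate, n_cognate, coverage, float(t_sim),
                                 seed)
        recs = simulate_replicates(cfg, n_replicates,
                                   base_seed=seed + 20_000 * (ti + 1))
        tracks = np.array([sdo_time(r, COGNATE).values[sites] for r in recs])
        site_mean = tracks.mean(axis=0)
        site_sd = tracks.std(axis=0, ddof=1)
        mean_occ = float(site_mean.mean())
        stable = (prev_mean is not None and prev_mean > 0 and
                  abs(mean_occ - prev_mean) <= rel_tol * prev_mean)
        rows.append({"t_sim": t_sim, "mean_occupancy": mean_occ,
                     "mean_sd": float(site_sd.mean()), "stable": stable})
        prev_mean = mean_occ
    return pd.DataFrame(rows)
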