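"""Adapting full-system parameters to a simulated DNA subsegment.

Simulating a short segment of a genome requires rescaling either the
molecule numbers (copy-number model: abundance scales with the length
ratio, association rate untouched — adequate for highly abundant
species) or the kinetics (association-rate model: abundance untouched,
``k_assoc`` recalibrated so the fraction of time spent on the DNA
matches a target — needed for low-copy species, where rounding the
copy number would distort the system).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .simulator import SimConfig, SpeciesParams, bound_time_fraction, simulate_replicates


def copy_number_scale(n_full: int, l_sub: int, l_full: int) -> int:
    """Copy-number model: round(n_full * l_sub / l_full).

    Intended for highly abundant species; the association rate is left
    unchanged.  A warning is raised if a non-empty species rounds to 0.
    """
    if not 0 < l_sub <= l_full:
        raise ValueError("need 0 < l_sub <= l_full")
    n_sub = int(round(n_full * l_sub / l_full))
    if n_full > 0 and n_sub == 0:
        warnings.warn("copy-number scaling removed the species from the "
                      "subsystem (rounded to 0 molecules)", stacklevel=2)
    return n_sub


@dataclass
class CalibrationStep:
    iterate: int
    k_assoc: float
    bound_fraction: float
    target: float


def _eval_bound_fraction(config: SimConfig, species: str, k: float,
                         n_eval: int, seed: int) -> float:
    sp_list = []
    for sp in config.species:
        sp_list.append(replace(sp, k_assoc=k) if sp.name == species else sp)
    cfg = SimConfig(dna_length=config.dna_length, species=sp_list,
                    t_end=config.t_end, seed=seed)
    recs = simulate_replicates(cfg, n_eval, base_seed=seed)
    return float(np.mean([bound_time_fraction(r, species) for r in recs]))


def calibrate_association_rate(target_bound_fraction: float, config: SimConfig,
                               species: str | None = None, tol: float = 0.02,
                               max_iter: int = 30, n_eval: int = 4,
                               seed: int = 0,
                               report: list[CalibrationStep] | None = None) -> float:
    """Association-rate model: find k_assoc reproducing a target bound-time
    fraction by stochastic bisection.

    The bound fraction is monotone increasing in ``k_assoc``, so a
    bracketing search converges despite simulation noise; each iterate
    is evaluated as the mean over ``n_eval`` short replicate runs.
    Returns the calibrated rate; raises if the bracket cannot be
    established or ``max_iter`` is exhausted outside tolerance.
    """
    if not 0 < target_bound_fraction < 1:
        raise ValueError("target_bound_fraction must be in (0, 1)")
    if species is None:
        species = config.species[0].name
    sp0 = config.species_by_name(species)
    k = sp0.k_assoc if sp0.k_assoc > 0 else 1.0

    def f(kk: float, it: int) -> float:
        val = _eval_bound_fraction(config, species, kk, n_eval, seed + 1000 * it)
        if report is not None:
            report.append(CalibrationStep(it, kk, val, target_bound_fraction))
        return val

    it = 0
    f_k = f(k, it)
    if abs(f_k - target_bound_fraction) <= tol:
        return k

    # establish a bracket by geometric expansion
    lo, hi = k, k
    f_lo, f_hi = f_k, f_k
    for _ in range(20):
        it += 1
        if f_hi < target_bound_fraction:
            hi *= 4.0
            f_hi = f(hi, it)
        elif f_lo > target_bound_fraction:
            lo /= 4.0
            f_lo = f(lo, it)
        else:
            break
        if it >= max_iter:
            raise RuntimeError("could not bracket the target bound fraction; "
                               f"best k={hi if f_hi < target_bound_fraction else lo}")
    if not (f_lo <= target_bound_fraction <= f_hi):
        raise RuntimeError("non-bracketing search range after expansion")

    best_k, best_gap = k, abs(f_k - target_bound_fraction)
    while it < max_iter:
        it += 1
        mid = float(np.sqrt(lo * hi))  # geometric midpoint: rates live on a log scale
        f_mid = f(mid, it)
        gap = abs(f_mid - target_bound_fraction)
        if gap < best_gap:
            best_k, best_gap = mid, gap
        if gap <= tol:
            return mid
        if f_mid < target_bound_fraction:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"max_iter exceeded; best iterate k={best_k:.6g} "
                       f"(|f - target| = {best_gap:.4g})")


def calibration_report_tsv(report: list[CalibrationStep], path) -> None:
    with open(path, "w") as fh:
        fh.write("iterate\tk_assoc\tbound_fraction\ttarget\n")
        for st in report:
            fh.write(f"{st.iterate}\t{st.k_assoc:.6g}\t{st.bound_fraction:.6g}\t"
                     f"{st.target:.6g}\n")
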