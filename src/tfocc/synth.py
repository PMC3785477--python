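"""Synthetic substrates: random DNA, planted binding sites, synthetic motifs.

These generators emulate the kind of substrate the occupancy study runs
on — a bacterial genomic segment carrying one dominant operator-like
site over a realistic background score spectrum — without requiring any
genome download.  All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .motifs import (ALPHABET, EnergyLandscape, Motif, energy_from_scores,
                     information_content, score_landscape, write_pfm)


def random_dna(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random DNA with P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[idx].tobytes().decode()


def _site_for_rank(motif: Motif, rank: int) -> str:
    """Rank-1 site = consensus; rank r carries r-1 mismatches placed at the
    lowest-information columns (mismatch = second most probable base)."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    cons_idx = np.argmax(motif.probs, axis=1)
    site = list(cons_idx)
    if rank > 1:
        # per-column information, ascending: weakest columns mutate first
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = motif.probs * (np.log2(motif.probs) -
                                   np.log2(motif.background)[None, :])
        col_ic = np.where(motif.probs > 0, terms, 0.0).sum(axis=1)
        order = np.argsort(col_ic, kind="stable")
        n_mut = min(rank - 1, motif.length)
        for col in order[:n_mut]:
            second = np.argsort(motif.probs[col])[-2]
            if second == site[col]:  # degenerate column: pick any other base
                second = (site[col] + 1) % 4
            site[col] = second
    return "".join(ALPHABET[i] for i in site)


def plant_sites(sequence: str, motif: Motif,
                placements: list[tuple[int, int]]) -> tuple[str, pd.DataFrame]:
    """Write motif sites into a sequence at given (position, strength rank).

    Returns the modified sequence and a truth manifest (position, strand,
    rank, planted sequence, planted forward-strand score).
    """
    w = motif.length
    seq = list(sequence)
    occupied: list[tuple[int, int]] = []
    rows = []
    for pos, rank in placements:
        if not 0 <= pos <= len(sequence) - w:
            raise ValueError(f"placement at {pos} out of range")
        for lo, hi in occupied:
            if pos < hi and lo < pos + w:
                raise ValueError(f"placements overlap at position {pos}")
        occupied.append((pos, pos + w))
        site = _site_for_rank(motif, rank)
        seq[pos: pos + w] = site
        rows.append({"position": pos, "strand": "+", "rank": rank,
                     "sequence": site})
    new_seq = "".join(seq)
    manifest = pd.DataFrame(rows, columns=["position", "strand", "rank", "sequence"])
    if len(manifest):
        track = score_landscape(motif, new_seq, strand_mode="forward")
        manifest["score"] = [track.scores[p, 0] for p in manifest["position"]]
    else:
        manifest["score"] = pd.Series(dtype=float)
    return new_seq, manifest


def synthetic_motif(length: int, target_ic: float, seed: int = 0) -> Motif:
    """Motif of given length whose information content hits ``target_ic``
    (within 0.1 bits; the construction is exact up to root-finding).

    Each column mixes a random consensus base with the uniform
    distribution, ``p = w * onehot + (1 - w) * uniform``; the single
    mixture weight w is solved so the total IC matches.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= target_ic <= 2 * length + 1e-9:
        raise ValueError(f"target_ic must be within [0, {2 * length}] bits")
    rng = np.random.default_rng(seed)
    cons = rng.integers(0, 4, size=length)

    def ic_of(w: float) -> float:
        p1 = w + (1 - w) / 4
        p0 = (1 - w) / 4
        per_col = p1 * np.log2(4 * p1) if p1 > 0 else 0.0
        if p0 > 0:
            per_col += 3 * p0 * np.log2(4 * p0)
        return length * per_col

    if target_ic <= 1e-9:
        w = 0.0
    elif target_ic >= 2 * length - 1e-9:
        w = 1.0
    else:
        w = brentq(lambda x: ic_of(x) - target_ic, 0.0, 1.0, xtol=1e-12)
    probs = np.full((length, 4), (1 - w) / 4)
    probs[np.arange(length), cons] += w
    return Motif(probs=probs)


def crowding_config(coverage: float, footprint: int, dna_length: int,
                    expected_bound_fraction: float) -> int:
    """Non-cognate abundance needed for a target DNA coverage fraction.

    ``abundance = round(coverage * dna_length /
    (footprint * expected_bound_fraction))`` — the expected bound
    fraction corrects for the time crowders spend in the 3D pool.
    """
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    if expected_bound_fraction <= 0:
        raise ValueError("expected_bound_fraction must be positive")
    abundance = int(round(coverage * dna_length /
                          (footprint * expected_bound_fraction)))
    if abundance * footprint > dna_length:
        import warnings
        warnings.warn("requested crowding demands more footprint than the DNA "
                      "can hold; realized coverage will fall short", stacklevel=2)
    return abundance


# ---------------------------------------------------------------------------
# the default study substrate


@dataclass
class Substrate:
    """A ready-to-simulate synthetic substrate."""

    sequence: str
    motif: Motif
    manifest: pd.DataFrame
    landscape: EnergyLandscape
    seed: int

    @property
    def dna_length(self) -> int:
        return len(self.sequence)

    def write(self, fasta_path, pfm_path, manifest_path) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(f">synthetic_substrate seed={self.seed}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i: i + 70] + "\n")
        write_pfm(self.motif, pfm_path, name=f"synthetic_motif seed={self.seed}")
        self.manifest.to_csv(manifest_path, sep="\t", index=False)


def make_substrate(seed: int, dna_length: int = 10_000, gc: float = 0.5,
                   motif_length: int = 21, motif_ic: float = 19.0,
                   site_position: int | None = None,
                   secondary_ranks: tuple[int, ...] = (3, 6),
                   top_site_energy: float = 5.0,
                   floor_quantile: float = 0.99, tau0: float = 1.0,
                   extra_placements: list[tuple[int, int]] | None = None) -> Substrate:
    """Build the default synthetic study substrate.

    Random DNA carrying one planted consensus site of a synthetic motif
    plus weaker auxiliary sites (``secondary_ranks``: mismatched variants,
    by default 2 and 5 mismatches) — the operator structure of a
    lac-repressor-like locus, one dominant site over a spectrum of weaker
    ones.  The score track is converted to energies with the scaling
    chosen so the planted (strongest) site sits ``top_site_energy`` kBT
    above the non-specific floor.  This pins the intensive quantity that
    controls site saturation, making substrates comparable across seeds.
    """
    sub_seed = seed % (2**31 - 1)
    motif = synthetic_motif(motif_length, motif_ic, seed=sub_seed + 7919)
    seq = random_dna(dna_length, gc=gc, seed=sub_seed)
    if site_position is None:
        site_position = dna_length // 2
    placements = [(site_position, 1)]
    for i, rank in enumerate(secondary_ranks):
        # spread auxiliary sites over the segment, away from the main site
        pos = (i + 1) * dna_length // (len(secondary_ranks) + 1)
        if abs(pos - site_position) < motif_length:
            pos += 2 * motif_length
        placements.append((pos, rank))
    placements += list(extra_placements or [])
    seq, manifest = plant_sites(seq, motif, placements)
    track = score_landscape(motif, seq, strand_mode="both")
    floor = float(np.quantile(track.scores, floor_quantile))
    gap = float(track.scores.max() - floor)
    if gap <= 0:
        raise ValueError("degenerate substrate: no score exceeds the floor")
    scaling = top_site_energy / gap
    landscape = energy_from_scores(track, scaling=scaling,
                                   floor_quantile=floor_quantile, tau0=tau0)
    return Substrate(sequence=seq, motif=motif, manifest=manifest,
                     landscape=landscape, seed=sub_seed)
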