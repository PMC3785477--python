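"""Motifs, PWM scoring and binding-energy landscapes.

A motif is a per-position nucleotide probability table (columns ordered
A, C, G, T) with an explicit background distribution.  Scanning a DNA
sequence with the log-odds scores of the motif yields a score track; the
score track is converted into a binding-energy landscape in units of kBT
(dimensionless, beta = 1) and, through a Boltzmann factor, into the mean
waiting time of a bound molecule at every start position::

    tau(p, s) = tau0 * exp(E(p, s))

with ``E = scaling * max(score - floor, 0)`` — positions scoring below a
quantile floor are treated as non-specific baseline (E = 0).

Coordinates are 0-based start positions; a motif of length ``w`` placed at
start ``p`` covers the half-open interval ``[p, p + w)``.  Reverse-strand
scores are computed on the reverse complement of each window and assigned
to the same start coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

UNIFORM_BACKGROUND = np.full(4, 0.25)


def _as_background(background) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must be a length-4 vector over A,C,G,T")
    if np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be non-negative and sum to 1")
    return bg


@dataclass(frozen=True)
class Motif:
    """Position probability matrix over A, C, G, T with a background model.

    probs : (length, 4) array, each row summing to 1.
    background : (4,) probability vector.
    pseudocount : the count added per nucleotide when the motif was built
        from site sequences (informational; 0 for motifs built directly
        from probabilities).
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be a (length, 4) matrix with length >= 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("each motif position must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", _as_background(self.background))

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-probability base at each position (ties: first in ACGT)."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self) -> np.ndarray:
        """Natural-log odds probs/background; -inf where prob is 0."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs) - np.log(self.background)[None, :]


def build_motif(site_sequences, pseudocount: float = 0.0,
                background=UNIFORM_BACKGROUND) -> Motif:
    """Build a motif from aligned equal-length binding-site sequences.

    ``probs[i][b] = (count of b at position i + pseudocount)
                    / (n_sites + 4 * pseudocount)``
    """
    sites = list(site_sequences)
    if not sites:
        raise ValueError("at least one site sequence is required")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("all site sequences must have equal length")
    counts = np.zeros((length, 4), dtype=float)
    for s in sites:
        for i, base in enumerate(s.upper()):
            if base not in _IDX:
                raise ValueError(f"non-ACGT symbol {base!r} in site sequence")
            counts[i, _IDX[base]] += 1.0
    probs = (counts + pseudocount) / (len(sites) + 4.0 * pseudocount)
    return Motif(probs=probs, background=background, pseudocount=pseudocount)


def information_content(motif: Motif) -> float:
    """Kullback–Leibler information content in bits.

    ``IC = sum_i sum_b p[i,b] * log2(p[i,b] / bg[b])`` with 0*log(0) := 0.
    """
    p = motif.probs
    bg = motif.background
    if np.any((bg == 0) & (p.sum(axis=0) > 0)):
        raise ValueError("zero background probability with non-zero motif probability")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(bg)[None, :])
    return float(np.sum(np.where(p > 0, terms, 0.0)))


def truncate_motif(motif: Motif, n_remove: int) -> Motif:
    """Drop the rightmost ``n_remove`` columns, lowering information content."""
    if not 0 <= n_remove < motif.length:
        raise ValueError("n_remove must satisfy 0 <= n_remove < motif length")
    if n_remove == 0:
        return motif
    return Motif(probs=motif.probs[: motif.length - n_remove].copy(),
                 background=motif.background, pseudocount=motif.pseudocount)


# ---------------------------------------------------------------------------
# sequence handling


def encode_sequence(sequence: str) -> np.ndarray:
    """ACGT -> 0..3; any ambiguity code (N, ...) -> -1."""
    table = np.full(128, -1, dtype=np.int64)
    for b, i in _IDX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return table[arr]


def read_fasta(path, record_id: str | None = None) -> str:
    """Read one sequence from a FASTA file.

    A multi-record file requires ``record_id``; a single-record file is
    used as-is.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} has {len(records)} records; specify record_id")
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise ValueError(f"record {record_id!r} not found in {path}")


def read_pfm(path) -> Motif:
    """Read a plain-text 4-row (A,C,G,T) x length matrix of counts or
    probabilities, whitespace separated; a leading '>' header is optional."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        # tolerate JASPAR-style "A [ 1 2 3 ]" rows
        line = line.lstrip("ACGT").strip().lstrip("[").rstrip("]")
        rows.append([float(x) for x in line.split()])
    if len(rows) != 4:
        raise ValueError(f"expected 4 matrix rows (A,C,G,T), got {len(rows)}")
    mat = np.asarray(rows, dtype=float).T  # (length, 4)
    sums = mat.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("matrix column with non-positive total")
    return Motif(probs=mat / sums)


def write_pfm(motif: Motif, path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(ALPHABET):
            fh.write(" ".join(f"{v:.6f}" for v in motif.probs[:, i]) + "\n")


# ---------------------------------------------------------------------------
# scoring and energies


@dataclass(frozen=True)
class ScoreTrack:
    """Log-odds scores per start position and strand.

    scores : (n_starts, n_strands); column 0 forward, column 1 reverse.
    ambiguous : boolean mask of starts whose window contained a
        non-ACGT symbol (those were scored as background, i.e. 0
        contribution from the ambiguous base).
    """

    scores: np.ndarray
    ambiguous: np.ndarray
    motif_length: int

    @property
    def n_starts(self) -> int:
        return self.scores.shape[0]

    @property
    def n_strands(self) -> int:
        return self.scores.shape[1]


def score_landscape(motif: Motif, sequence: str | np.ndarray,
                    strand_mode: str = "both") -> ScoreTrack:
    """Scan a sequence with the motif's log-odds scores.

    Valid starts are ``[0, L - w]``.  Ambiguous nucleotides contribute a
    background score (0) and flag the window.
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError("strand_mode must be 'both' or 'forward'")
    enc = encode_sequence(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    w = motif.length
    if enc.size < w:
        raise ValueError("sequence shorter than motif")
    lo = motif.log_odds()
    n_starts = enc.size - w + 1
    n_strands = 2 if strand_mode == "both" else 1
    scores = np.zeros((n_starts, n_strands))
    ambiguous = np.zeros(n_starts, dtype=bool)

    safe = np.where(enc >= 0, enc, 0)
    amb = enc < 0
    for i in range(w):
        col = safe[i : i + n_starts]
        contrib = lo[i, col]
        contrib = np.where(amb[i : i + n_starts], 0.0, contrib)
        scores[:, 0] += contrib
        ambiguous |= amb[i : i + n_starts]
        if n_strands == 2:
            # reverse strand: window reverse-complemented, same start coord
            rc_col = _COMPLEMENT_IDX[col]
            rc_contrib = lo[w - 1 - i, rc_col]
            scores[:, 1] += np.where(amb[i : i + n_starts], 0.0, rc_contrib)
    return ScoreTrack(scores=scores, ambiguous=ambiguous, motif_length=w)


@dataclass(frozen=True)
class EnergyLandscape:
    """Binding energies (kBT units, >= 0) and waiting times per (start, strand).

    The defining relation is ``waiting_times = tau0 * exp(energies)``;
    energy 0 is the non-specific baseline, so waiting times are never
    below ``tau0``.
    """

    energies: np.ndarray
    tau0: float
    scaling: float
    footprint: int

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 2 or e.shape[0] < 1:
            raise ValueError("energies must be (n_starts, n_strands)")
        if np.any(e < 0):
            raise ValueError("energies must be >= 0 (non-specific baseline is 0)")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        object.__setattr__(self, "energies", e)

    @property
    def waiting_times(self) -> np.ndarray:
        return self.tau0 * np.exp(self.energies)

    @property
    def n_starts(self) -> int:
        return self.energies.shape[0]

    @property
    def n_strands(self) -> int:
        return self.energies.shape[1]

    def site_energy(self) -> np.ndarray:
        """Per-start site strength: the stronger strand's energy."""
        return self.energies.max(axis=1)


def energy_from_scores(scores: ScoreTrack | np.ndarray, scaling: float = 1.0,
                       floor_quantile: float = 0.99, tau0: float = 1.0,
                       footprint: int | None = None) -> EnergyLandscape:
    """Convert a score track to a binding-energy landscape.

    ``E = scaling * max(score - floor, 0)`` where the floor is the
    ``floor_quantile`` quantile of all scores: the bulk of positions below
    it are non-specific (E = 0, waiting time tau0).
    """
    if isinstance(scores, ScoreTrack):
        arr = scores.scores
        if footprint is None:
            footprint = scores.motif_length
    else:
        arr = np.asarray(scores, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if footprint is None:
            raise ValueError("footprint required when passing a bare score array")
    if arr.size == 0:
        raise ValueError("empty score track")
    if scaling <= 0:
        raise ValueError("scaling must be positive")
    if not 0 <= floor_quantile < 1:
        raise ValueError("floor_quantile must be in [0, 1)")
    floor = float(np.quantile(arr, floor_quantile))
    energies = scaling * np.clip(arr - floor, 0.0, None)
    return EnergyLandscape(energies=energies, tau0=tau0, scaling=scaling,
                           footprint=int(footprint))


def flat_landscape(n_starts: int, tau0: float = 1.0, footprint: int = 1) -> EnergyLandscape:
    """Sequence-independent landscape (non-cognate species): E = 0 everywhere."""
    return EnergyLandscape(energies=np.zeros((n_starts, 1)), tau0=tau0,
                           scaling=1.0, footprint=footprint)


# ---------------------------------------------------------------------------
# track export


def landscape_to_tsv(track: ScoreTrack, landscape: EnergyLandscape, path) -> None:
    """TSV of (position, strand, score, energy, tau)."""
    strands = "+-"
    with open(path, "w") as fh:
        fh.write("position\tstrand\tscore\tenergy\ttau\n")
        for s in range(landscape.n_strands):
            for p in range(landscape.n_starts):
                fh.write(
                    f"{p}\t{strands[s]}\t{track.scores[p, s]:.6g}\t"
                    f"{landscape.energies[p, s]:.6g}\t"
                    f"{landscape.tau0 * math.exp(landscape.energies[p, s]):.6g}\n")


def write_bedgraph(values, path, chrom: str = "seq", span: int = 1) -> None:
    """Minimal bedGraph writer: one interval [p, p+span) per value."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}"\n')
        for p, v in enumerate(values):
            fh.write(f"{chrom}\t{p}\t{p + span}\t{v:.6g}\n")
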