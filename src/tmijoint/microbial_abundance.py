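"""Microbial relative abundance from ambiguously mapped reads via EM.

A read that maps to several candidate genomes is resolved probabilistically:
mixture weights over genomes are fit by expectation-maximization of

    sum_r log sum_j pi_j * p(r | j),   p(r|j) ~ (1/len_j) * eps^m * (1-eps)^(L-m)

where ``m`` is the mismatch count of the read against genome ``j``. The
reported abundance is the genome-length-corrected weight, i.e. proportional to
``pi_j / len_j`` (abundance of genomes, not of reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO


class AbundanceError(ValueError):
    pass


@dataclass
class AlignmentCandidateSet:
    """Read-to-genome alignment candidates plus genome lengths.

    ``entries`` holds ``(read_id, genome_id, mismatch_count)`` triples;
    secondary hits are first-class citizens here, they carry the ambiguity
    signal the EM resolves.
    """

    entries: list[tuple[str, str, int]]
    genome_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for read_id, genome_id, mism in self.entries:
            if genome_id not in self.genome_lengths:
                raise AbundanceError(
                    f"genome {genome_id!r} (read {read_id!r}) missing from length table"
                )
            if mism < 0:
                raise AbundanceError(f"negative mismatch count for read {read_id!r}")

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genome_lengths)

    def dedup(self) -> "AlignmentCandidateSet":
        """Keep the best (lowest mismatch) entry per (read, genome) pair."""
        best: dict[tuple[str, str], int] = {}
        for read_id, genome_id, mism in self.entries:
            key = (read_id, genome_id)
            if key not in best or mism < best[key]:
                best[key] = mism
        entries = [(r, g, m) for (r, g), m in best.items()]
        return AlignmentCandidateSet(entries, dict(self.genome_lengths))


@dataclass
class AbundanceProfile:
    """Relative abundance per genome plus the EM diagnostics."""

    abundances: dict[str, float]
    read_fractions: dict[str, float]
    n_reads_used: int
    n_reads_dropped: int
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    def as_array(self, order: list[str] | None = None) -> np.ndarray:
        order = order or sorted(self.abundances)
        return np.array([self.abundances[g] for g in order])


def em_abundance(
    cands: AlignmentCandidateSet,
    error_rate: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceProfile:
    """Fit mixture weights over genomes by EM and length-correct them.

    The E-step assigns each read fractional responsibilities over its
    candidate genomes; the M-step sets each weight to the mean responsibility.
    Iteration stops once the log-likelihood gain drops below ``tol``. The
    log-likelihood trace is non-decreasing by construction (EM ascent) and is
    asserted as such. Reads with no candidates are dropped and counted.

    Deterministic: initialization is uniform, no randomness involved.
    """
    if not 0.0 < error_rate < 1.0:
        raise AbundanceError("error_rate must lie strictly in (0, 1)")
    cands = cands.dedup()
    if not cands.entries:
        raise AbundanceError("no candidates: empty alignment set")

    genomes = cands.genome_ids
    g_index = {g: i for i, g in enumerate(genomes)}
    n_genomes = len(genomes)
    lengths = np.array([cands.genome_lengths[g] for g in genomes], dtype=float)
    if np.any(lengths <= 0):
        raise AbundanceError("genome lengths must be positive")

    # flat entry arrays sorted by read so reduceat can do per-read reductions
    reads = sorted({r for r, _, _ in cands.entries})
    r_index = {r: i for i, r in enumerate(reads)}
    order = sorted(range(len(cands.entries)), key=lambda k: r_index[cands.entries[k][0]])
    read_of = np.array([r_index[cands.entries[k][0]] for k in order])
    genome_of = np.array([g_index[cands.entries[k][1]] for k in order])
    mismatches = np.array([cands.entries[k][2] for k in order], dtype=float)
    starts = np.searchsorted(read_of, np.arange(len(reads)))
    n_reads = len(reads)

    # log p(r|j) up to a per-read constant; the constant cancels in the
    # E-step and only shifts the trace, so monotonicity is unaffected.
    log_odds = math.log(error_rate) - math.log1p(-error_rate)
    logp = -np.log(lengths[genome_of]) + mismatches * log_odds
    if not np.all(np.isfinite(logp)):
        raise AbundanceError("numerical underflow in candidate likelihoods")

    log_pi = np.full(n_genomes, -math.log(n_genomes))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        joint = log_pi[genome_of] + logp
        per_read = np.logaddexp.reduceat(joint, starts)
        loglik = float(per_read.sum())
        if trace and loglik < trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        if trace and loglik - trace[-1] < tol:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        resp = np.exp(joint - per_read[read_of])
        pi = np.bincount(genome_of, weights=resp, minlength=n_genomes) / n_reads
        with np.errstate(divide="ignore"):
            log_pi = np.log(pi)

    pi = np.exp(log_pi)
    pi /= pi.sum()
    corrected = pi / lengths
    corrected /= corrected.sum()
    return AbundanceProfile(
        abundances={g: float(corrected[i]) for i, g in enumerate(genomes)},
        read_fractions={g: float(pi[i]) for i, g in enumerate(genomes)},
        n_reads_used=n_reads,
        n_reads_dropped=0,
        loglik_trace=trace,
        n_iterations=it,
        converged=converged,
    )


def shannon_diversity(profile: AbundanceProfile | dict[str, float] | np.ndarray) -> float:
    """Shannon index H = -sum p ln p in nats; zero proportions contribute 0."""
    if isinstance(profile, AbundanceProfile):
        p = profile.as_array()
    elif isinstance(profile, dict):
        p = np.array(list(profile.values()), dtype=float)
    else:
        p = np.asarray(profile, dtype=float)
    if np.any(p < 0):
        raise AbundanceError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise AbundanceError(f"profile not normalized (sum={p.sum():.6g})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def load_genome_lengths(path: str | Path) -> dict[str, int]:
    """Genome lengths from a 2-column TSV (id, length) or a FASTA file."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genome_id, length = line.split("\t")[:2]
            lengths[genome_id] = int(length)
    return lengths


def parse_alignment_candidates(
    path: str | Path, genome_lengths: dict[str, int] | None = None
) -> AlignmentCandidateSet:
    """Build a candidate set from SAM/BAM (NM tag = mismatches, secondaries
    kept) or from a 3-column TSV ``read_id<TAB>genome_id<TAB>mismatches``.

    For SAM input, genome lengths default to the @SQ header. Duplicate
    (read, genome) rows collapse to the lowest mismatch count.
    """
    path = Path(path)
    entries: list[tuple[str, str, int]] = []
    if path.suffix.lower() in (".sam", ".bam"):
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as handle:
            header_lengths = {
                sq["SN"]: int(sq["LN"]) for sq in handle.header.get("SQ", [])
            }
            for aln in handle.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                mism = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
                entries.append((aln.query_name, aln.reference_name, mism))
        genome_lengths = genome_lengths or header_lengths
    else:
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                read_id, genome_id, mism = line.split("\t")[:3]
                entries.append((read_id, genome_id, int(mism)))
    if not entries:
        raise AbundanceError(f"no candidates parsed from {path}")
    if genome_lengths is None:
        raise AbundanceError("genome_lengths required for TSV candidate input")
    return AlignmentCandidateSet(entries, dict(genome_lengths)).dedup()


def write_abundance_tsv(profile: AbundanceProfile, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("genome_id\tabundance\tread_fraction\n")
        for genome in sorted(profile.abundances):
            handle.write(
                f"{genome}\t{profile.abundances[genome]:.10g}"
                f"\t{profile.read_fractions[genome]:.10g}\n"
            )
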