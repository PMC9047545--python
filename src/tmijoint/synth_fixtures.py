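"""Deterministic synthetic data for every pipeline stage.

All generators are pure functions of a :class:`SynthSpec`: the same spec
(seed included) reproduces bit-identical outputs. They cover signature
matrices, noisy mixtures with known fractions, toy genomes with ambiguous
read mappings, QC-challenge read sets and paired cohorts with planted fold
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv_svr import CellFractionTable, MixtureMatrix, SignatureMatrix
from .microbial_abundance import AlignmentCandidateSet
from .seqio_reads import ReadRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SynthSpec:
    """Knobs for all synthetic generators; one RNG stream per call, seeded."""

    seed: int = 0
    # expression / deconvolution
    n_genes: int = 200
    m_cell_types: int = 5
    L_samples: int = 20
    noise_sd: float = 0.05  # fraction of the mean clean signal
    marker_fold: float = 8.0
    # genomes / reads
    n_genomes: int = 3
    genome_length: int = 2000
    n_reads: int = 1000
    read_length: int = 50
    error_rate: float = 0.01
    ambiguous_fraction: float = 0.2
    genome_proportions: tuple[float, ...] | None = None  # default: uniform
    # cohort
    n_pairs: int = 49
    n_bacteria: int = 8
    planted_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_genes", "m_cell_types", "L_samples", "n_genomes",
                     "genome_length", "n_reads", "read_length", "n_pairs", "n_bacteria"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noise_sd", "error_rate", "ambiguous_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_signature(spec: SynthSpec) -> SignatureMatrix:
    """Block-structured signature: each cell type gets a contiguous marker
    gene block elevated by ``marker_fold`` over a positive baseline."""
    rng = np.random.default_rng(spec.seed)
    baseline = rng.uniform(0.5, 1.5, size=(spec.n_genes, spec.m_cell_types))
    blocks = np.array_split(np.arange(spec.n_genes), spec.m_cell_types)
    for j, block in enumerate(blocks):
        baseline[block, j] *= spec.marker_fold
    genes = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    types = [f"cell_{j}" for j in range(spec.m_cell_types)]
    return SignatureMatrix(pd.DataFrame(baseline, index=genes, columns=types))


def make_mixtures(
    S: SignatureMatrix, spec: SynthSpec
) -> tuple[MixtureMatrix, CellFractionTable]:
    """Mixtures X = S f + truncated Gaussian noise, f ~ flat Dirichlet."""
    rng = np.random.default_rng(spec.seed + 1)
    m = len(S.cell_type_ids)
    fractions = rng.dirichlet(np.ones(m), size=spec.L_samples)  # L x m
    clean = S.values.to_numpy() @ fractions.T  # genes x L
    sd = spec.noise_sd * clean.mean()
    noisy = clean if sd == 0 else np.clip(clean + rng.normal(0.0, sd, clean.shape), 0.0, None)
    samples = [f"sample_{i:03d}" for i in range(spec.L_samples)]
    X = MixtureMatrix(pd.DataFrame(noisy, index=S.gene_ids, columns=samples))
    truth = CellFractionTable(
        pd.DataFrame(fractions, index=samples, columns=S.cell_type_ids)
    )
    return X, truth


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    arr = np.array(list(seq))
    err = rng.random(arr.size) < error_rate
    for pos in np.flatnonzero(err):
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr), int(err.sum())


def make_read_set(
    spec: SynthSpec,
) -> tuple[list[ReadRecord], dict[str, float], AlignmentCandidateSet]:
    """Reads sampled from toy genomes at known proportions with per-base error.

    All genomes share one identical subsequence; reads drawn from it align
    equally well everywhere, inducing ``ambiguous_fraction`` of multi-mapping
    reads. Returns the reads, the truth proportions and the candidate set an
    aligner would report (ambiguous reads get one equal-mismatch candidate
    per genome).
    """
    rng = np.random.default_rng(spec.seed + 2)
    if spec.genome_length < 3 * spec.read_length:
        raise ValueError("genome_length must be at least 3x read_length")
    n_g = spec.n_genomes
    props = (
        np.full(n_g, 1.0 / n_g)
        if spec.genome_proportions is None
        else np.asarray(spec.genome_proportions, dtype=float)
    )
    if props.size != n_g or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("genome_proportions must be a length-n_genomes simplex vector")

    shared_len = 2 * spec.read_length
    shared = _random_genome(rng, shared_len)
    genomes: dict[str, str] = {}
    for g in range(n_g):
        body = _random_genome(rng, spec.genome_length - shared_len)
        genomes[f"genome_{g}"] = shared + body  # shared block at the start
    genome_ids = list(genomes)
    lengths = {g: len(s) for g, s in genomes.items()}

    reads: list[ReadRecord] = []
    entries: list[tuple[str, str, int]] = []
    max_shared_start = shared_len - spec.read_length
    quals = [35] * spec.read_length
    for i in range(spec.n_reads):
        g_idx = int(rng.choice(n_g, p=props))
        genome_id = genome_ids[g_idx]
        ambiguous = rng.random() < spec.ambiguous_fraction
        if ambiguous:
            start = int(rng.integers(0, max_shared_start + 1))
        else:
            start = int(rng.integers(shared_len, lengths[genome_id] - spec.read_length + 1))
        fragment = genomes[genome_id][start : start + spec.read_length]
        seq, n_err = _mutate(rng, fragment, spec.error_rate)
        read_id = f"read_{i:06d}"
        reads.append(ReadRecord(read_id, seq, qualities=list(quals), flag=4))
        if ambiguous:
            entries.extend((read_id, g, n_err) for g in genome_ids)
        else:
            entries.append((read_id, genome_id, n_err))
    truth = {genome_ids[j]: float(props[j]) for j in range(n_g)}
    return reads, truth, AlignmentCandidateSet(entries, lengths)


def make_cohort(
    spec: SynthSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired tumor/normal cohort with planted fold changes.

    Returns (bacteria abundances, cell fractions, labels); both feature
    blocks are compositional (rows sum to 1, renormalized after planting).
    ``planted_effects`` maps feature names (``bact_<i>`` / ``cell_<j>``) to
    the fold change applied to the tumor arm.
    """
    rng = np.random.default_rng(spec.seed + 3)
    n_b, n_c = spec.n_bacteria, spec.m_cell_types

    def _block(prefix: str, n_feat: int) -> tuple[pd.DataFrame, list[str]]:
        base = rng.dirichlet(np.ones(n_feat) * 5.0, size=spec.n_pairs)
        names = [f"{prefix}_{i}" for i in range(n_feat)]
        rows, index = [], []
        for pair in range(spec.n_pairs):
            for arm in ("N", "T"):
                # paired design: shared baseline + arm-specific lognormal jitter
                vals = base[pair] * rng.lognormal(0.0, 0.3, size=n_feat)
                if arm == "T":
                    for j, name in enumerate(names):
                        fold = spec.planted_effects.get(name)
                        if fold is not None:
                            vals[j] *= fold
                vals = vals / vals.sum()
                rows.append(vals)
                index.append(f"P{pair:03d}_{arm}")
        return pd.DataFrame(rows, index=index, columns=names), index

    bacteria, index = _block("bact", n_b)
    cells, _ = _block("cell", n_c)
    labels = pd.Series(
        [1 if sid.endswith("_T") else 0 for sid in index], index=index, name="label"
    )
    return bacteria, cells, labels
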