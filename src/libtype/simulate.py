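"""Synthetic composition signatures and FASTQ files.

Stand-in for a repository-derived reference database: each supported
library type gets a stylized per-position base-probability model that
encodes the protocol's known compositional fingerprint.

* ``genomic`` — flat curves at the organism's GC content (a ChIP-seq
  style library: most reads come from non-enriched genome, so the
  composition mirrors genomic GC; 41% for human, 42% for mouse).
* ``bisulfite`` — conversion of unmethylated C to T leaves only a small
  residual cytosine fraction (methylated CpGs) at every position.
* ``atac`` — Tn5 target-sequence preference imprints a positional bias
  at the read start, decaying geometrically to the genomic baseline by
  position 12.
* ``chiapet`` — the ligated linker produces a near-deterministic base
  pattern in the middle of the read (positions 17-25).
* ``rnaseq`` — random-priming bias perturbs the first ~10 positions,
  milder than the Tn5 bias and with a different shape.

The shapes are qualitative encodings of these mechanisms, not fits to
any particular dataset; amplitudes default to the 5-15 percentage-point
deviations routinely seen in per-base-content QC plots of real
libraries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .composition import DEFAULT_MAX_POSITIONS, CompositionProfile
from .database import ReferenceDatabase, SampleRecord, database_from_profiles

logger = logging.getLogger(__name__)

SIGNATURE_TYPES = ("genomic", "bisulfite", "atac", "chiapet", "rnaseq")

DEFAULT_GC_PERCENT = 41.0  # human; 42 for mouse
DEFAULT_C_RESIDUAL = 0.02
DEFAULT_ATAC_AMPLITUDE = 0.15
DEFAULT_ATAC_DECAY = 0.7
DEFAULT_ATAC_POSITIONS = 12
DEFAULT_RNA_AMPLITUDE = 0.10
DEFAULT_RNA_DECAY = 0.8
DEFAULT_RNA_POSITIONS = 10
DEFAULT_LINKER = "GTTGGATAA"  # synthetic 9-mer spanning positions 17-25
DEFAULT_LINKER_START = 16  # 0-based; user-facing position 17
DEFAULT_LINKER_DOMINANCE = 0.88
DEFAULT_JITTER_CONCENTRATION = 2000.0

# zero-sum unit-norm perturbation directions over (A, C, G, T), cycled
# along the read so the bias wiggles rather than shifting one base only
_ATAC_PATTERNS = np.array(
    [
        [1.0, -1.0, 1.0, -1.0],
        [-1.0, 1.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0, 1.0],
    ]
) / 2.0
_RNA_PATTERNS = np.array(
    [
        [1.0, -1.0, -1.0, 1.0],
        [-1.0, -1.0, 1.0, 1.0],
        [1.0, 1.0, -1.0, -1.0],
    ]
) / 2.0

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SignatureModel:
    """Expected A/C/G/T fraction at each read position for one library type."""

    name: str
    base_probs: np.ndarray  # L x 4, rows sum to 1
    description: str = ""

    def __post_init__(self) -> None:
        self.base_probs = np.asarray(self.base_probs, dtype=float)
        if self.base_probs.ndim != 2 or self.base_probs.shape[1] != 4:
            raise ValueError("base_probs must be L x 4 over A,C,G,T")
        if ((self.base_probs < 0) | (self.base_probs > 1)).any():
            raise ValueError("base probabilities must lie in [0, 1]")
        if not np.allclose(self.base_probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("base probability rows must sum to 1")

    @property
    def positions(self) -> int:
        return self.base_probs.shape[0]


def _genomic_rows(L: int, gc_percent: float) -> np.ndarray:
    gc = gc_percent / 100.0
    at = (1.0 - gc) / 2.0
    row = np.array([at, gc / 2.0, gc / 2.0, at])  # A, C, G, T
    return np.tile(row, (L, 1))


def _start_bias(
    base: np.ndarray, patterns: np.ndarray, amplitude: float, decay: float, n_pos: int
) -> np.ndarray:
    probs = base.copy()
    for p in range(min(n_pos, probs.shape[0])):
        probs[p] += amplitude * decay**p * patterns[p % len(patterns)]
    return np.clip(probs, 1e-6, 1.0)


def make_signature(
    type_name: str,
    L: int = DEFAULT_MAX_POSITIONS,
    gc_percent: float = DEFAULT_GC_PERCENT,
    c_residual: float = DEFAULT_C_RESIDUAL,
    atac_amplitude: float = DEFAULT_ATAC_AMPLITUDE,
    atac_decay: float = DEFAULT_ATAC_DECAY,
    atac_positions: int = DEFAULT_ATAC_POSITIONS,
    rna_amplitude: float = DEFAULT_RNA_AMPLITUDE,
    rna_decay: float = DEFAULT_RNA_DECAY,
    rna_positions: int = DEFAULT_RNA_POSITIONS,
    linker: str = DEFAULT_LINKER,
    linker_start: int = DEFAULT_LINKER_START,
    linker_dominance: float = DEFAULT_LINKER_DOMINANCE,
) -> SignatureModel:
    """Build the positional base-probability model for one library type."""
    if type_name not in SIGNATURE_TYPES:
        raise ValueError(
            f"unknown signature type {type_name!r}; valid types: {', '.join(SIGNATURE_TYPES)}"
        )
    base = _genomic_rows(L, gc_percent)
    if type_name == "genomic":
        probs = base
        desc = f"flat genomic composition at {gc_percent}% GC (ChIP-seq style)"
    elif type_name == "bisulfite":
        probs = base.copy()
        deficit = probs[:, 1] - c_residual
        probs[:, 1] = c_residual
        probs[:, 3] += deficit  # unconverted C reads as T
        desc = f"bisulfite-converted: C reduced to {c_residual:.2%}, deficit moved to T"
    elif type_name == "atac":
        probs = _start_bias(base, _ATAC_PATTERNS, atac_amplitude, atac_decay, atac_positions)
        desc = "Tn5 insertion bias over the read start, geometric decay to baseline"
    elif type_name == "chiapet":
        probs = base.copy()
        off = (1.0 - linker_dominance) / 3.0
        for k, b in enumerate(linker):
            p = linker_start + k
            if p >= L:
                break
            probs[p] = off
            probs[p, _BASE_INDEX[b.upper()]] = linker_dominance
        desc = f"linker {linker} dominating positions {linker_start + 1}-{linker_start + len(linker)}"
    else:  # rnaseq
        probs = _start_bias(base, _RNA_PATTERNS, rna_amplitude, rna_decay, rna_positions)
        desc = "random-priming bias over the first positions, milder than Tn5"
    probs = probs / probs.sum(axis=1, keepdims=True)
    return SignatureModel(name=type_name, base_probs=probs, description=desc)


def jitter_signature(
    sig: SignatureModel, rng: np.random.Generator,
    concentration: float = DEFAULT_JITTER_CONCENTRATION,
) -> SignatureModel:
    """Dirichlet-perturb each row so samples within a type are not identical."""
    if not concentration:
        return sig
    rows = np.stack(
        [rng.dirichlet(np.maximum(row, 1e-9) * concentration) for row in sig.base_probs]
    )
    return SignatureModel(name=sig.name, base_probs=rows, description=sig.description)


def sample_profile(
    sig: SignatureModel, n_reads: int, seed: int = 0, sample_id: str | None = None
) -> CompositionProfile:
    """Multinomial draw of per-position base counts (no N calls)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros((sig.positions, 5), dtype=np.int64)
    for p in range(sig.positions):
        counts[p, :4] = rng.multinomial(n_reads, sig.base_probs[p])
    return CompositionProfile(
        sample_id=sample_id or f"{sig.name}_sim",
        counts=counts,
        reads_sampled=n_reads,
        reads_total=n_reads,
        seed=seed,
    )


def generate_fastq(
    sig: SignatureModel,
    n_reads: int,
    path: str | Path,
    read_len: int | None = None,
    seed: int = 0,
    chunk: int = 50_000,
) -> Path:
    """Write a synthetic FASTQ whose composition follows the signature.

    The first L bases of each read are drawn independently per position
    from the signature rows; positions beyond L reuse the last row.
    Quality is a constant dummy.  A ``.gz`` suffix triggers gzip output.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    path = Path(path)
    L = sig.positions
    read_len = read_len or L
    if read_len < L:
        raise ValueError(f"read_len must be >= signature length {L}")
    rng = np.random.default_rng(seed)
    probs = np.vstack([sig.base_probs, np.tile(sig.base_probs[-1], (read_len - L, 1))])
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = "I" * read_len
    opener = gzip.open if path.suffix == ".gz" else open
    written = 0
    with opener(path, "wt") as fh:  # type: ignore[operator]
        while written < n_reads:
            n = min(chunk, n_reads - written)
            codes = np.empty((n, read_len), dtype=np.uint8)
            u = rng.random((n, read_len))
            for p in range(read_len):
                codes[:, p] = np.searchsorted(cum[p], u[:, p], side="right")
            seqs = alphabet[codes].view(f"S{read_len}")[:, 0]
            parts = []
            for i, s in enumerate(seqs):
                parts.append(f"@{sig.name}_{written + i}\n{s.decode()}\n+\n{qual}\n")
            fh.write("".join(parts))
            written += n
    logger.info("wrote %d synthetic %s reads to %s", n_reads, sig.name, path)
    return path


def generate_reference_db(
    n_per_type: int = 50,
    types: tuple[str, ...] = SIGNATURE_TYPES,
    seed: int = 0,
    n_reads: int = 100_000,
    L: int = DEFAULT_MAX_POSITIONS,
    gc_percent: float = DEFAULT_GC_PERCENT,
    jitter_concentration: float = DEFAULT_JITTER_CONCENTRATION,
    species: str = "synthetic",
) -> ReferenceDatabase:
    """Labelled synthetic database: ``n_per_type`` jittered samples per type."""
    rng = np.random.default_rng(seed)
    records = []
    for t in types:
        sig = make_signature(t, L=L, gc_percent=gc_percent)
        for i in range(n_per_type):
            jit = jitter_signature(sig, rng, concentration=jitter_concentration)
            profile_seed = int(rng.integers(0, 2**31 - 1))
            prof = sample_profile(jit, n_reads, seed=profile_seed, sample_id=f"{t}_{i:03d}")
            records.append(
                SampleRecord(
                    sample_id=f"{t}_{i:03d}", library_type=t,
                    profile=prof, species=species,
                )
            )
    return database_from_profiles(records)
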