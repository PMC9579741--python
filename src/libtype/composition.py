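"""Per-position base composition of sequencing libraries.

The central pre-mapping QC signal used throughout this package is the
per-position base content of a library: for each of the leading read
positions (50 by default), how many sampled reads carry A, C, G, T or N
there.  Library preparation protocols imprint characteristic shapes on
these curves (bisulfite conversion depletes C, Tn5 tagmentation biases
the read start, ChIA-PET linkers dominate the read middle), which is what
makes the composition profile informative about library type.

Only read1 of paired-end data is profiled; a mate file, if supplied to
the CLI, is ignored with a logged notice.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGTN"
DEFAULT_MAX_POSITIONS = 50
DEFAULT_SAMPLE_READS = 100_000

# byte -> base code (A=0 C=1 G=2 T=3, everything else N=4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_PAD = 0  # '\0' never occurs in a sequence line


class FastqError(ValueError):
    """Malformed FASTQ input."""


@dataclass(frozen=True)
class FastqRecord:
    """One 4-line FASTQ record (identifier, sequence, quality)."""

    identifier: str
    sequence: str
    quality: str


@dataclass
class CompositionProfile:
    """Per-position A/C/G/T/N counts for one library.

    ``counts`` is an ``L x 5`` integer table over the bases A, C, G, T, N.
    At every position the base counts sum to the number of sampled reads
    long enough to cover it, so columns beyond the shortest read may have
    totals below ``reads_sampled``.
    """

    sample_id: str
    counts: np.ndarray
    reads_sampled: int
    reads_total: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValueError("counts must be an L x 5 table over A,C,G,T,N")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        totals = self.counts.sum(axis=1)
        if (totals > self.reads_sampled).any():
            raise ValueError("position total exceeds reads_sampled")

    @property
    def positions(self) -> int:
        return self.counts.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.reads_sampled == other.reads_sampled
            and self.reads_total == other.reads_total
            and self.counts.shape == other.counts.shape
            and bool((self.counts == other.counts).all())
        )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))  # type: ignore[arg-type]
    return open(path, "rt")


def stream_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a plain or gzip FASTQ file.

    Yields records in file order without loading the whole file.
    Lowercase bases are uppercased here; bases outside {A,C,G,T} are
    counted as N later, at tabulation.

    Raises :class:`FastqError` naming the 1-based record index for a
    record with mismatched sequence/quality lengths or a trailing
    partial record, and for an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records = 0
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if header == "":
                break
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            n_records += 1
            if any(ln == "" for ln in lines):
                raise FastqError(
                    f"{path}: truncated FASTQ record {n_records} "
                    "(line count not a multiple of 4)"
                )
            ident, seq, plus, qual = (ln.rstrip("\n").rstrip("\r") for ln in lines)
            if not ident.startswith("@") or not plus.startswith("+"):
                raise FastqError(
                    f"{path}: record {n_records} does not follow the "
                    "4-line FASTQ layout ('@' header / '+' separator)"
                )
            if len(seq) != len(qual):
                raise FastqError(
                    f"{path}: record {n_records} sequence/quality length "
                    f"mismatch ({len(seq)} vs {len(qual)})"
                )
            yield FastqRecord(ident[1:], seq.upper(), qual)
    if n_records == 0:
        raise FastqError(f"{path}: empty FASTQ file")


def reservoir_sample(
    records: Iterable[FastqRecord], k: int, seed: int = 0
) -> tuple[list[FastqRecord], int]:
    """Uniform single-pass subsample of ``k`` records (Algorithm R).

    Returns ``(sample, reads_total)``.  If the stream holds at most ``k``
    records they are all returned.  Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: list[FastqRecord] = []
    total = 0
    for rec in records:
        total += 1
        if total <= k:
            reservoir.append(rec)
        else:
            j = int(rng.integers(0, total))
            if j < k:
                reservoir[j] = rec
    return reservoir, total


def tabulate_composition(
    reads: list[FastqRecord],
    max_positions: int = DEFAULT_MAX_POSITIONS,
    sample_id: str = "sample",
    reads_total: int | None = None,
    seed: int | None = None,
) -> CompositionProfile:
    """Count bases at the first ``max_positions`` positions of the reads.

    Reads shorter than ``max_positions`` contribute only up to their
    length.  Any base outside {A,C,G,T} (after uppercasing) counts as N.
    """
    if not reads:
        raise ValueError("cannot tabulate an empty read list")
    L = max_positions
    n = len(reads)
    arr = np.full((n, L), _PAD, dtype=np.uint8)
    for i, rec in enumerate(reads):
        s = rec.sequence[:L].upper().encode("ascii", errors="replace")
        arr[i, : len(s)] = np.frombuffer(s, dtype=np.uint8)
    covered = arr != _PAD
    codes = _CODE[arr]
    counts = np.zeros((L, 5), dtype=np.int64)
    for b in range(5):
        counts[:, b] = ((codes == b) & covered).sum(axis=0)
    return CompositionProfile(
        sample_id=sample_id,
        counts=counts,
        reads_sampled=n,
        reads_total=n if reads_total is None else reads_total,
        seed=seed,
    )


def profile_fastq(
    path: str | Path,
    max_positions: int = DEFAULT_MAX_POSITIONS,
    sample_reads: int = DEFAULT_SAMPLE_READS,
    seed: int = 0,
    sample_id: str | None = None,
) -> CompositionProfile:
    """FASTQ file -> composition profile (stream, subsample, tabulate)."""
    sample, total = reservoir_sample(stream_fastq(path), sample_reads, seed=seed)
    sid = sample_id if sample_id is not None else Path(path).name
    for suffix in (".gz", ".fastq", ".fq"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return tabulate_composition(
        sample, max_positions=max_positions, sample_id=sid,
        reads_total=total, seed=seed,
    )


def to_percentages(
    profile: CompositionProfile,
    include_n: bool = False,
    strict: bool = False,
) -> np.ndarray:
    """Convert counts to per-position percentages.

    With ``include_n`` false (the default used for feature vectors and
    plotting), N calls are excluded from the denominator and the A/C/G/T
    percentages renormalise to 100.  Positions with zero usable total are
    NaN rows with a warning, or an error in ``strict`` mode; downstream
    feature building imputes them from the database-wide mean.
    """
    k = 5 if include_n else 4
    counts = profile.counts[:, :k].astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        positions = ", ".join(str(p + 1) for p in np.flatnonzero(zero)[:10])
        if strict:
            raise ValueError(
                f"{profile.sample_id}: zero usable coverage at position(s) {positions}"
            )
        warnings.warn(
            f"{profile.sample_id}: zero usable coverage at position(s) "
            f"{positions}; percentages set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / totals[:, None]
    pct[zero] = np.nan
    return pct


# ---------------------------------------------------------------------------
# profile file format: '#' metadata lines, then a TSV of integer counts with
# 1-based position labels (matching the usual per-base-content plot axis).

_PROFILE_COLUMNS = ["position", "A", "C", "G", "T", "N"]


def write_profile(profile: CompositionProfile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write(f"# sample_id\t{profile.sample_id}\n")
        fh.write(f"# reads_sampled\t{profile.reads_sampled}\n")
        fh.write(f"# reads_total\t{profile.reads_total}\n")
        fh.write(f"# seed\t{'' if profile.seed is None else profile.seed}\n")
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for p in range(profile.positions):
            row = "\t".join(str(int(c)) for c in profile.counts[p])
            fh.write(f"{p + 1}\t{row}\n")


def read_profile(path: str | Path) -> CompositionProfile:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "rt") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    if list(table.columns) != _PROFILE_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_PROFILE_COLUMNS}, found {list(table.columns)}"
        )
    counts = table[list("ACGTN")].to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError(f"{path}: base counts must be integers")
    seed = meta.get("seed", "")
    return CompositionProfile(
        sample_id=meta.get("sample_id", path.stem),
        counts=counts,
        reads_sampled=int(meta.get("reads_sampled", counts.sum(axis=1).max())),
        reads_total=int(meta.get("reads_total", counts.sum(axis=1).max())),
        seed=int(seed) if seed else None,
    )
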