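"""Reference-database reduction: uniform fraction and count-matched sampling
of FASTA sequence databases.

Profile search against a 50-million-sequence database dominates the cost of
PSSM feature generation.  Uniformly subsampling the database (to k% of its
records, or to the record count of a similarity-reduced variant) cuts that
cost roughly proportionally while keeping the sampled records byte-identical
to the source.  Sampling is reservoir-based (single streaming pass, memory
proportional to the sample), without replacement, order-preserving, and fully
determined by the seed.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceDatabase",
    "SamplePlan",
    "FastaFormatError",
    "count_sequences",
    "sample_size_for_fraction",
    "sample_database",
    "hit_count_report",
]


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (e.g. a record with an empty header)."""


@dataclass
class SequenceDatabase:
    path: str
    n_sequences: int


@dataclass(frozen=True)
class SamplePlan:
    """How to subsample: ``mode="fraction"`` keeps ceil(n·k/100) records,
    ``mode="count"`` keeps exactly ``target_count`` records."""

    mode: str
    k_percent: float | None = None
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "fraction":
            if self.k_percent is None or not 0 < self.k_percent <= 100:
                raise ValueError("fraction mode needs 0 < k_percent <= 100")
        elif self.mode == "count":
            if self.target_count is None or self.target_count < 1:
                raise ValueError("count mode needs target_count >= 1")
        else:
            raise ValueError(f"unknown sampling mode {self.mode!r}")

    def size_for(self, n: int) -> int:
        if self.mode == "fraction":
            return sample_size_for_fraction(n, self.k_percent)
        assert self.target_count is not None
        return self.target_count


def _iter_fasta(path: str):
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            if not title.strip():
                raise FastaFormatError(f"record with empty header in {path}")
            yield title, seq


def count_sequences(db_path: str) -> int:
    """Exact FASTA record count in a single constant-memory pass."""
    return sum(1 for _ in _iter_fasta(db_path))


def sample_size_for_fraction(n: int, k_percent: float) -> int:
    """Records to keep for a k% sample: ceil(n · k / 100).

    Exact rational arithmetic avoids floating-point boundary errors on large
    n; the ceiling rule keeps every sample non-empty for any k > 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < k_percent <= 100:
        raise ValueError("k_percent must lie in (0, 100]")
    target = Fraction(n) * Fraction(str(k_percent)) / 100
    return int(-(-target.numerator // target.denominator))


def sample_database(
    db: SequenceDatabase | str, plan: SamplePlan, out_path: str
) -> SequenceDatabase:
    """Uniformly sample records without replacement into a new FASTA file.

    Output preserves the source record order (stable subset) and each record
    is written byte-identically.  Reservoir sampling (algorithm R) keeps only
    the sample in memory, so multi-gigabyte inputs stream through.  A manifest
    JSON (source path and SHA-256, seed, counts) is written next to the
    output.
    """
    src_path = db.path if isinstance(db, SequenceDatabase) else db
    n_known = db.n_sequences if isinstance(db, SequenceDatabase) else None
    if plan.mode == "fraction":
        n = n_known if n_known is not None else count_sequences(src_path)
        target = plan.size_for(n)
    else:
        target = plan.size_for(0)

    rng = random.Random(plan.seed)
    reservoir: list[tuple[int, str, str]] = []
    n_seen = 0
    for title, seq in _iter_fasta(src_path):
        if n_seen < target:
            reservoir.append((n_seen, title, seq))
        else:
            j = rng.randrange(n_seen + 1)
            if j < target:
                reservoir[j] = (n_seen, title, seq)
        n_seen += 1
    if target > n_seen:
        raise ValueError(f"target {target} exceeds database size {n_seen}")

    reservoir.sort(key=lambda rec: rec[0])  # restore source order
    with open(out_path, "w") as out:
        for _, title, seq in reservoir:
            out.write(f">{title}\n{seq}\n")

    manifest = {
        "source": str(src_path),
        "source_sha256": _sha256(src_path),
        "source_records": n_seen,
        "mode": plan.mode,
        "k_percent": plan.k_percent,
        "target_count": plan.target_count,
        "seed": plan.seed,
        "sampled_records": len(reservoir),
    }
    Path(str(out_path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return SequenceDatabase(path=str(out_path), n_sequences=len(reservoir))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def hit_count_report(profiles: list, ndigits: int | None = None) -> float:
    """Mean PSI-BLAST hit count over profiles that carry one.

    Profiles missing ``n_hits`` are excluded with a warning; the mean is
    optionally rounded to ``ndigits``.
    """
    import warnings

    hits = [p.n_hits for p in profiles if p.n_hits is not None]
    skipped = len(profiles) - len(hits)
    if skipped:
        warnings.warn(f"{skipped} profile(s) missing n_hits were excluded")
    if not hits:
        raise ValueError("no profiles carry a hit count")
    mean = float(np.mean(hits))
    return round(mean, ndigits) if ndigits is not None else mean
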