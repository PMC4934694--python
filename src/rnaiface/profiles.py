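"""PSSM profiles: generation via PSI-BLAST, parsing, logistic normalization,
and the NSSD / NKL profile distance metrics.

A position-specific scoring matrix (PSSM) is an L×20 matrix of log-odds scores
describing per-position residue conservation of a query protein, produced by
iterative profile search against a reference database.  Columns follow the
canonical PSI-BLAST order ``A R N D C Q E G H I L K M F P S T W Y V``
throughout.

Two distances compare same-query profiles built against different reference
databases:

* NSSD — the sum of squared entry differences divided by ``20·L``.
* NKL  — the symmetrized Kullback-Leibler sum divided by ``2·(20·L)``, with
  natural logarithms, applied entrywise to logistic-normalized profiles
  (entries must be strictly positive for the logarithms to be defined).
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit

ALPHABET = "ARNDCQEGHILKMFPSTWYV"

__all__ = [
    "ALPHABET",
    "PSSMProfile",
    "NormalizedProfile",
    "PSSMFormatError",
    "ToolUnavailableError",
    "run_psiblast",
    "psiblast_command",
    "parse_pssm",
    "write_pssm",
    "normalize_logistic",
    "pseudo_profile",
    "nssd",
    "nkl",
    "mean_pairwise_distance",
]


class PSSMFormatError(ValueError):
    """Raised when ASCII PSSM text cannot be parsed."""


class ToolUnavailableError(RuntimeError):
    """Raised when the external PSI-BLAST binary is not on PATH."""


@dataclass
class PSSMProfile:
    """Raw log-odds profile: L rows, 20 columns in canonical order."""

    sequence: str
    scores: np.ndarray
    n_hits: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"scores must be {len(self.sequence)}x20, got {self.scores.shape}"
            )


@dataclass
class NormalizedProfile:
    """Logistic-normalized profile: every entry strictly in (0, 1)."""

    sequence: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequence), 20):
            raise ValueError(
                f"values must be {len(self.sequence)}x20, got {self.values.shape}"
            )
        if not ((self.values > 0) & (self.values < 1)).all():
            raise ValueError("normalized profile entries must lie strictly in (0, 1)")


def psiblast_command(
    query_path: str,
    database_path: str,
    pssm_path: str,
    report_path: str,
    iterations: int = 3,
    evalue: float = 0.001,
    threads: int = 1,
    binary: str = "psiblast",
) -> list[str]:
    """Assemble the PSI-BLAST command line (exposed for dry-run inspection)."""
    return [
        binary,
        "-query", query_path,
        "-db", database_path,
        "-num_iterations", str(iterations),
        "-evalue", str(evalue),
        "-inclusion_ethresh", str(evalue),
        "-num_threads", str(threads),
        "-out_ascii_pssm", pssm_path,
        "-outfmt", "7",
        "-out", report_path,
    ]


def run_psiblast(
    sequence: str,
    database_path: str,
    iterations: int = 3,
    evalue: float = 0.001,
    threads: int = 1,
    binary: str = "psiblast",
    dry_run: bool = False,
) -> PSSMProfile | list[str]:
    """Run PSI-BLAST and return the final-iteration ASCII PSSM as a profile.

    The search runs the configured number of iterations with the given e-value
    used both for reporting and for profile inclusion.  ``n_hits`` records the
    number of hits found in the final iteration.  With ``dry_run=True`` the
    assembled command list is returned without executing anything.
    """
    if shutil.which(binary) is None and not dry_run:
        raise ToolUnavailableError(
            f"{binary!r} not found on PATH; use pseudo_profile() as an offline fallback"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        query = tmpdir / "query.fasta"
        pssm = tmpdir / "query.pssm"
        report = tmpdir / "hits.tsv"
        cmd = psiblast_command(
            str(query), database_path, str(pssm), str(report),
            iterations=iterations, evalue=evalue, threads=threads, binary=binary,
        )
        if dry_run:
            return cmd
        query.write_text(f">query\n{sequence}\n")
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"psiblast failed: {proc.stderr.strip()}")
        n_hits = _final_hit_count(report.read_text()) if report.exists() else 0
        if not pssm.exists():
            # no hits at all: PSI-BLAST backs the matrix with BLOSUM62 scores
            profile = pseudo_profile(sequence)
            profile.n_hits = 0
            return profile
        profile = parse_pssm(pssm.read_text())
        profile.n_hits = n_hits
        return profile


def _final_hit_count(report_text: str) -> int:
    counts = re.findall(r"#\s*(\d+)\s+hits found", report_text)
    return int(counts[-1]) if counts else 0


def parse_pssm(ascii_text: str) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Rows carry a 1-based position, the query residue, 20 integer log-odds
    scores, and (optionally) 20 weighted observed percentages plus trailing
    statistics, which are ignored.
    """
    sequence = []
    rows = []
    n_header_cols = 0
    for lineno, line in enumerate(ascii_text.splitlines(), start=1):
        stripped = line.strip()
        if not n_header_cols:
            parts = stripped.split()
            if parts[:20] == list(ALPHABET):
                n_header_cols = len(parts)  # 20, or 40 with the percentage block
            continue
        if not stripped:
            break  # blank line terminates the matrix; trailer follows
        parts = stripped.split()
        if not parts[0].isdigit():
            break
        if not rows:
            row_len = len(parts)
        if len(parts) < 2 + n_header_cols or len(parts) != row_len:
            raise PSSMFormatError(
                f"line {lineno}: expected {n_header_cols} score columns"
            )
        idx, code, scores = int(parts[0]), parts[1], parts[2:22]
        if idx != len(rows) + 1:
            raise PSSMFormatError(f"line {lineno}: row index {idx} out of order")
        try:
            rows.append([int(s) for s in scores])
        except ValueError as exc:
            raise PSSMFormatError(f"line {lineno}: non-integer score") from exc
        sequence.append(code)
    if not rows:
        raise PSSMFormatError("no PSSM matrix found in text")
    return PSSMProfile(sequence="".join(sequence), scores=np.array(rows, dtype=float))


def write_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile back to the ASCII PSSM dialect (lossless for the
    integer score block; the percentage block is written as zeros)."""
    header = " ".join(f"{a:>3}" for a in ALPHABET)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"         {header}  {header}",
    ]
    for i, (code, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        scores = " ".join(f"{int(round(x)):>3}" for x in row)
        zeros = " ".join(f"{0:>3}" for _ in range(20))
        lines.append(f"{i:>5} {code}  {scores}  {zeros}  0.00 0.00")
    lines.append("")
    return "\n".join(lines) + "\n"


def normalize_logistic(profile: PSSMProfile) -> NormalizedProfile:
    """Map each raw score x to 1/(1+e^-x), squashing log-odds into (0, 1)."""
    return NormalizedProfile(sequence=profile.sequence, values=expit(profile.scores))


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ROWS = {
    aa: np.array([_BLOSUM62[aa, b] for b in ALPHABET], dtype=float) for aa in ALPHABET
}


def pseudo_profile(sequence: str) -> PSSMProfile:
    """Deterministic offline stand-in for a PSI-BLAST profile.

    Row i is the BLOSUM62 substitution-score row of residue i, reordered to
    the canonical column order; ``'X'`` rows are all zeros (the neutral score).
    This matches what PSI-BLAST itself falls back to when a search yields no
    usable hits, and lets the downstream pipeline run without the external
    binary or a reference database.
    """
    rows = []
    for aa in sequence:
        if aa in _BLOSUM_ROWS:
            rows.append(_BLOSUM_ROWS[aa])
        elif aa == "X":
            rows.append(np.zeros(20))
        else:
            raise ValueError(f"unknown residue code {aa!r}")
    return PSSMProfile(sequence=sequence, scores=np.array(rows), n_hits=None)


def _check_pair(p1: NormalizedProfile, p2: NormalizedProfile) -> None:
    for p in (p1, p2):
        if not isinstance(p, NormalizedProfile):
            raise TypeError(
                "profile distances are defined on NormalizedProfile inputs; "
                "apply normalize_logistic() to raw profiles first"
            )
    if p1.values.shape != p2.values.shape:
        raise ValueError(f"shape mismatch: {p1.values.shape} vs {p2.values.shape}")


def nssd(p1: NormalizedProfile, p2: NormalizedProfile) -> float:
    """Normalized sum of squared differences: mean squared entry difference
    over all 20·L cells.  Symmetric, zero iff identical, and bounded by 1 for
    entries in (0, 1)."""
    _check_pair(p1, p2)
    return float(np.mean((p1.values - p2.values) ** 2))


def nkl(p1: NormalizedProfile, p2: NormalizedProfile) -> float:
    """Symmetrized Kullback-Leibler sum over all cells, divided by 2·(20·L).

    Natural logarithms are used, applied entrywise to the logistic-normalized
    values without row renormalization.  Non-negative termwise and symmetric.
    """
    _check_pair(p1, p2)
    a, b = p1.values, p2.values
    if not ((a > 0).all() and (b > 0).all()):
        raise ValueError("NKL requires strictly positive entries")
    total = np.sum(a * np.log(a / b) + b * np.log(b / a))
    return float(total / (2.0 * a.size))


def mean_pairwise_distance(
    profiles_a: list[NormalizedProfile],
    profiles_b: list[NormalizedProfile],
    metric: str = "nssd",
) -> float:
    """Arithmetic mean of per-query distances between paired profile lists.

    Lists must be aligned by query: same order, same sequences.  Used to
    compare the profile sets produced by two different reference databases.
    """
    if len(profiles_a) != len(profiles_b):
        raise ValueError("profile lists must have equal length")
    if not profiles_a:
        raise ValueError("profile lists are empty")
    fn = {"nssd": nssd, "nkl": nkl}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    distances = []
    for pa, pb in zip(profiles_a, profiles_b):
        if pa.sequence != pb.sequence:
            raise ValueError("paired profiles must share the query sequence")
        distances.append(fn(pa, pb))
    return float(np.mean(distances))
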