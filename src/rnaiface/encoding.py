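"""Window feature encoding: normalized profiles + labels -> fixed-width vectors.

Each residue is encoded by the 20-value normalized-profile rows of a
contiguous, odd-length sequence window centred on it (default 25 residues:
the target flanked by 12 neighbours on each side), concatenated into a single
vector of ``window * 20`` features — 500 with the defaults.  Window positions
that fall off either terminus contribute a constant pad value in all 20 slots;
the default pad 0.5 is the logistic image of a raw score of 0, i.e. the
"no information" point of the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import NormalizedProfile
from .structures import InterfaceAnnotation

__all__ = ["WindowConfig", "LabeledDataset", "encode_residue", "encode_chain", "assemble"]


@dataclass(frozen=True)
class WindowConfig:
    window: int = 25
    pad_value: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if not 0.0 < self.pad_value < 1.0:
            raise ValueError("pad_value must lie in (0, 1)")

    @property
    def flank(self) -> int:
        return (self.window - 1) // 2

    @property
    def n_features(self) -> int:
        return self.window * 20


@dataclass
class LabeledDataset:
    """Per-residue feature vectors with labels and chain provenance.

    ``provenance[i]`` is the ``(chain_id, 1-based position)`` the i-th row was
    encoded from, so chain-level bookkeeping (cross-validation folds, leakage
    audits) stays possible after assembly.
    """

    vectors: np.ndarray  # N x (window*20)
    labels: np.ndarray  # N, binary
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if not (len(self.vectors) == len(self.labels) == len(self.provenance)):
            raise ValueError("vectors, labels and provenance must be aligned")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_interface(self) -> int:
        return int(self.labels.sum())

    @property
    def n_non_interface(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.provenance:
            seen.setdefault(cid)
        return list(seen)

    def subset_chains(self, chain_ids: set[str]) -> "LabeledDataset":
        mask = np.array([cid in chain_ids for cid, _ in self.provenance])
        prov = [p for p, m in zip(self.provenance, mask) if m]
        return LabeledDataset(self.vectors[mask], self.labels[mask], prov)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=[f"f{i}" for i in range(self.n_features)])
        df.insert(0, "chain", [c for c, _ in self.provenance])
        df.insert(1, "position", [p for _, p in self.provenance])
        df["label"] = self.labels
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        feats = [c for c in df.columns if c.startswith("f")]
        return cls(
            df[feats].to_numpy(float),
            df["label"].to_numpy(int),
            list(zip(df["chain"].astype(str), df["position"].astype(int))),
        )

    def save_npz(self, path: str) -> None:
        np.savez_compressed(
            path,
            vectors=self.vectors,
            labels=self.labels,
            chains=np.array([c for c, _ in self.provenance]),
            positions=np.array([p for _, p in self.provenance]),
        )

    @classmethod
    def load_npz(cls, path: str) -> "LabeledDataset":
        data = np.load(path, allow_pickle=False)
        prov = list(zip((str(c) for c in data["chains"]), (int(p) for p in data["positions"])))
        return cls(data["vectors"], data["labels"], prov)


def encode_residue(
    profile: NormalizedProfile, position: int, config: WindowConfig = WindowConfig()
) -> np.ndarray:
    """Encode the residue at 1-based ``position`` as a window feature vector."""
    L = len(profile.sequence)
    if not 1 <= position <= L:
        raise IndexError(f"position {position} outside 1..{L}")
    rows = []
    for offset in range(-config.flank, config.flank + 1):
        p = position + offset
        if 1 <= p <= L:
            rows.append(profile.values[p - 1])
        else:
            rows.append(np.full(20, config.pad_value))
    return np.concatenate(rows)


def encode_chain(
    profile: NormalizedProfile,
    annotation: InterfaceAnnotation,
    config: WindowConfig = WindowConfig(),
) -> LabeledDataset:
    """Encode every residue of a chain; labels come from the annotation."""
    if profile.sequence != annotation.sequence:
        raise ValueError(
            f"profile/annotation sequence mismatch for chain {annotation.chain_id!r}"
        )
    L = len(profile.sequence)
    vectors = np.stack([encode_residue(profile, i, config) for i in range(1, L + 1)])
    provenance = [(annotation.chain_id, i) for i in range(1, L + 1)]
    return LabeledDataset(vectors, annotation.labels.copy(), provenance)


def assemble(datasets: list[LabeledDataset]) -> LabeledDataset:
    """Row-concatenate chain datasets, preserving provenance."""
    if not datasets:
        raise ValueError("no datasets to assemble")
    widths = {d.n_features for d in datasets}
    if len(widths) != 1:
        raise ValueError(f"feature-width mismatch across datasets: {sorted(widths)}")
    return LabeledDataset(
        np.vstack([d.vectors for d in datasets]),
        np.concatenate([d.labels for d in datasets]),
        [p for d in datasets for p in d.provenance],
    )
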