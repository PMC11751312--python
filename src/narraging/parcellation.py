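"""Parcellation table: node -> (name, network, hemisphere).

The analyses retain four association networks of a 7-network cortical
parcellation — default mode (DMN), frontoparietal (FPN), dorsal attention
(DAN) and ventral attention (VAN) — giving 236 nodes by default.  Node ids
are 1-based in files and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NETWORKS = ("DMN", "FPN", "DAN", "VAN")

#: per-network node counts of the default 236-node parcellation, proportioned
#: like the four association networks of a 400-parcel 7-network atlas
DEFAULT_NETWORK_SIZES = {"DMN": 90, "FPN": 60, "DAN": 42, "VAN": 44}


@dataclass(frozen=True)
class ParcelNode:
    node_id: int  # 1-based, file-facing
    name: str
    network: str
    hemisphere: str


@dataclass
class Parcellation:
    """Ordered node table shared by every matrix of a cohort."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"node_id", "name", "network", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        if self.table["node_id"].duplicated().any():
            raise ValueError("duplicate node_id in parcellation")
        bad = set(self.table["network"]) - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown networks in parcellation: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> tuple[str, ...]:
        return NETWORKS

    def network_of(self, node: int) -> str:
        """Network label of a 0-based node index."""
        return self.table["network"].iloc[node]

    def network_labels(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    def network_nodes(self, network: str) -> np.ndarray:
        """0-based node indices belonging to ``network``."""
        if network not in NETWORKS:
            raise KeyError(f"unknown network {network!r}")
        return np.nonzero(self.table["network"].to_numpy() == network)[0]

    def network_size(self, network: str) -> int:
        return int(self.network_nodes(network).size)

    def nodes(self) -> list[ParcelNode]:
        return [ParcelNode(int(r.node_id), r.name, r.network, r.hemisphere)
                for r in self.table.itertuples()]

    def content_hash(self) -> str:
        import hashlib

        payload = self.table.to_csv(sep="\t", index=False).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # ---- I/O ----

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_parcellation(n_nodes: int = 236) -> Parcellation:
    """Synthetic parcellation with network proportions of the default atlas.

    The retained four-network subset of the real atlas is user-supplied in
    practice; this constructor produces a plausible stand-in with the same
    proportions at any node count (used by the simulator and tests).
    """
    total = sum(DEFAULT_NETWORK_SIZES.values())
    sizes = {k: max(1, round(v * n_nodes / total)) for k, v in DEFAULT_NETWORK_SIZES.items()}
    # fix rounding drift on the largest network
    drift = n_nodes - sum(sizes.values())
    sizes["DMN"] += drift
    rows = []
    node_id = 1
    for net in NETWORKS:
        for i in range(sizes[net]):
            hemi = "L" if i % 2 == 0 else "R"
            rows.append((node_id, f"{net}_{hemi}_{i + 1}", net, hemi))
            node_id += 1
    table = pd.DataFrame(rows, columns=["node_id", "name", "network", "hemisphere"])
    return Parcellation(table)
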