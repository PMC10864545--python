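"""Gene-panel definitions for the proteasome subunit analysis.

A :class:`GenePanel` is an ordered set of gene symbols, each annotated with the
structural role the encoded subunit plays in the 26S proteasome (20S alpha/beta
rings, 19S ATPase base, non-ATPase base, lid, assembly chaperones, activators).
The packaged default panel holds 41 subunit genes; the alpha-ring genes
(PSMA1-PSMA7) and PSMC6 additionally define the composite-marker feature set.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

VALID_ROLES = frozenset(
    {"alpha", "beta", "base_ATPase", "base_nonATPase", "lid", "assembly", "activator"}
)

ALPHA_RING = ("PSMA1", "PSMA2", "PSMA3", "PSMA4", "PSMA5", "PSMA6", "PSMA7")

#: Hub triple used for the network disorder metrics (determinant / entropy).
HUB_TRIPLE = ("PSMA2", "PSMA4", "PSMC6")


@dataclass(frozen=True)
class GenePanel:
    """Ordered, uniquely-named gene panel with per-gene structural roles."""

    symbols: tuple[str, ...]
    roles: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            dupes = sorted({s for s in self.symbols if list(self.symbols).count(s) > 1})
            raise ValueError(f"duplicate panel symbols: {dupes}")
        missing = [s for s in self.symbols if s not in self.roles]
        if missing:
            raise ValueError(f"symbols without a role: {missing}")
        bad = sorted({r for r in self.roles.values() if r not in VALID_ROLES})
        if bad:
            raise ValueError(f"unknown roles {bad}; valid roles are {sorted(VALID_ROLES)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.roles

    def with_role(self, role: str) -> tuple[str, ...]:
        """Symbols carrying ``role``, in panel order."""
        return tuple(s for s in self.symbols if self.roles[s] == role)

    @property
    def alpha_ring(self) -> tuple[str, ...]:
        """The seven 20S outer-ring genes, required by the marker operations."""
        alpha = self.with_role("alpha")
        if alpha != ALPHA_RING:
            raise ValueError(
                f"marker operations require the alpha role to be exactly "
                f"PSMA1-PSMA7 in order; panel has {alpha}"
            )
        return alpha

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "GenePanel":
        return cls(symbols=tuple(mapping), roles=dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenePanel":
        """Load a panel from a YAML or JSON file with a ``symbols:`` mapping."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict) or "symbols" not in data:
            raise ValueError(f"panel file {path} must contain a 'symbols' mapping")
        return cls.from_mapping(data["symbols"])

    @classmethod
    def default(cls) -> "GenePanel":
        """The packaged 41-gene proteasome subunit panel."""
        ref = resources.files("proteocohere").joinpath("data/default_panel.yaml")
        data = yaml.safe_load(ref.read_text())
        return cls.from_mapping(data["symbols"])
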