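"""Immune lineage marker panels (mouse gene symbols, ImmPort-derived).

The four panels are used verbatim, as opaque case-sensitive symbols: B cell,
T cell, housekeeping reference, and lymph-node macrophage markers. The
housekeeping panel has low between-sample variability and serves as the
denominator of contamination ratios.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name}: duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


BCELL = MarkerPanel("bcell", (
    "Blnk", "Btk", "Cd19", "Cd79a", "Cd79b", "Cr2", "Fcgr2b", "Ighg3", "Ighm",
))

TCELL = MarkerPanel("tcell", (
    "Cd247", "Cd28", "Cd3d", "Cd3e", "Cd3g", "Cd4", "Cd40lg", "Cd8a",
    "Cd8b1", "Icos", "Zap70",
))

HOUSEKEEPING = MarkerPanel("housekeeping", (
    "Rpl37a", "B2m", "Hmbs", "Stx5a", "Psmb2", "Hnrnpab", "Actb", "Qars",
))

MACROPHAGE = MarkerPanel("macrophage", (
    "Csf1r", "Cd45", "Siglec1", "Cd48", "Lyz2", "Fos", "Nr4a1", "H2-k1",
    "Ly6e",
))

CANONICAL_PANELS: dict[str, MarkerPanel] = {
    p.name: p for p in (BCELL, TCELL, HOUSEKEEPING, MACROPHAGE)
}

#: lineage label attached to each marker gene in synthetic truth tables
LINEAGE_OF_PANEL = {"bcell": "B", "tcell": "T",
                    "housekeeping": "housekeeping", "macrophage": "macrophage"}


def panels_from_yaml(mapping: dict) -> dict[str, MarkerPanel]:
    """Build custom panels from a ``{name: [genes...]}`` mapping."""
    return {name: MarkerPanel(name, tuple(genes))
            for name, genes in mapping.items()}
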