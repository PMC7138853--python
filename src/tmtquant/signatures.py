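"""Threshold-based significant-protein calling and cross-species signature
intersection via a user-supplied homolog map.

A protein enters the up (down) signature when its log2 fold change exceeds
the threshold in the corresponding direction AND both its p-value and BH
q-value clear their cutoffs — all inequalities strict.  Mouse symbols are
translated to human symbols through a two-column homolog table (applied
case-insensitively; one-to-many mappings expand), and the cross-species
signature is the per-direction intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import pandas as pd


@dataclass
class SignatureThresholds:
    max_p: float = 0.05
    max_q: float = 0.1
    min_log2fc: float = 1.0

    def validate(self) -> None:
        for name in ("max_p", "max_q", "min_log2fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.max_p > 1:
            raise ValueError("max_p: must be <= 1")


def significant_proteins(de: pd.DataFrame,
                         thresholds: SignatureThresholds | None = None,
                         direction: str = "up") -> set:
    """Genes passing the significance cutoffs in one direction.

    up: ``log2fc > min_log2fc``; down: ``log2fc < -min_log2fc``; both
    require ``p < max_p`` and ``q < max_q`` (strict, as the cutoffs are
    printed).  The up and down sets are disjoint for any table.
    """
    thresholds = thresholds or SignatureThresholds()
    thresholds.validate()
    if direction not in ("up", "down"):
        raise ValueError("direction: must be 'up' or 'down'")
    for col in ("log2fc", "p", "q"):
        if col not in de.columns:
            raise ValueError(f"DE table lacks required column {col!r}")
    base = (de["p"] < thresholds.max_p) & (de["q"] < thresholds.max_q)
    if direction == "up":
        sel = base & (de["log2fc"] > thresholds.min_log2fc)
    else:
        sel = base & (de["log2fc"] < -thresholds.min_log2fc)
    return set(de.index[sel.fillna(False)])


def load_homolog_map(path) -> pd.DataFrame:
    """Read a two-column (source, target) homolog table from TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("homolog map needs two columns (source, target)")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return df


@dataclass
class MappingReport:
    mapped: set
    unmapped: list
    expanded: dict = field(default_factory=dict)   # source -> multiple targets


def map_homologs(genes, homolog_map: pd.DataFrame) -> MappingReport:
    """Translate symbols through the homolog map (case-insensitive).

    One-to-many mappings expand to all targets (logged in ``expanded``);
    unmapped symbols are reported, never silently dropped.
    """
    if len(homolog_map) == 0:
        raise ValueError("empty homolog map")
    lut: dict = {}
    for src, tgt in zip(homolog_map["source"], homolog_map["target"]):
        lut.setdefault(str(src).lower(), []).append(str(tgt))
    mapped, unmapped, expanded = set(), [], {}
    for g in genes:
        targets = lut.get(str(g).lower())
        if targets is None:
            unmapped.append(g)
            continue
        if len(targets) > 1:
            expanded[g] = list(targets)
        mapped.update(targets)
    if expanded:
        warnings.warn(
            f"{len(expanded)} symbols expanded to multiple homologs")
    return MappingReport(mapped, unmapped, expanded)


@dataclass
class OverlapSignature:
    """Cross-species signature: per-direction intersections and Venn counts."""

    up: set
    down: set
    venn: dict                # direction -> region -> count
    membership: pd.DataFrame  # per gene: flags for each input set
    provenance: tuple = ("human", "mouse")


def _looks_mouse(symbol: str) -> bool:
    return symbol != symbol.upper() and symbol[:1].isupper()


def overlap_signature(human_up, human_down, mouse_up_mapped,
                      mouse_down_mapped) -> OverlapSignature:
    """Intersect human and homolog-mapped mouse signatures per direction.

    Venn region counts are reported for both directions; mouse-style
    (title-case) symbols inside a human set trigger a namespace warning.
    """
    human_up, human_down = set(human_up), set(human_down)
    mouse_up, mouse_down = set(mouse_up_mapped), set(mouse_down_mapped)
    suspicious = [g for g in (human_up | human_down) if _looks_mouse(g)]
    if suspicious:
        warnings.warn(
            f"possible namespace mixing: mouse-style symbols in a human set: "
            f"{sorted(suspicious)[:5]}")
    up = human_up & mouse_up
    down = human_down & mouse_down
    venn = {
        "up": {"human_only": len(human_up - mouse_up),
               "mouse_only": len(mouse_up - human_up),
               "shared": len(up)},
        "down": {"human_only": len(human_down - mouse_down),
                 "mouse_only": len(mouse_down - human_down),
                 "shared": len(down)},
    }
    genes = sorted(human_up | human_down | mouse_up | mouse_down)
    membership = pd.DataFrame(
        {
            "human_up": [g in human_up for g in genes],
            "human_down": [g in human_down for g in genes],
            "mouse_up": [g in mouse_up for g in genes],
            "mouse_down": [g in mouse_down for g in genes],
            "signature_up": [g in up for g in genes],
            "signature_down": [g in down for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return OverlapSignature(up, down, venn, membership)
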