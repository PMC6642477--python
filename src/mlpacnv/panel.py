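"""Probe-panel model for an MLPA pharmacogene CNV assay.

An MLPA probe mix is a fixed set of ligation probes whose amplification
products are resolved by length on a capillary sequencer.  Three probe
roles matter downstream:

* ``target`` probes interrogate exons of the genes under study (here 40
  regions over 11 cytochrome-P450 genes and 3 glutathione-S-transferase
  genes);
* ``reference`` probes sit in copy-number-stable regions and anchor the
  within-sample normalization;
* control fragments (four DNA-quantity Q-fragments, three denaturation
  D-fragments, one X- and one Y-fragment) carry no dosage information but
  report assay quality and sample sex.

Every later stage (simulation, normalization, calling) is keyed to a
:class:`PanelDef`, so the panel is validated eagerly and round-trips
losslessly through a small JSON format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ProbeDef",
    "PanelDef",
    "PanelError",
    "PROBE_KINDS",
    "PANEL_GENES",
    "DEFAULT_GRID",
    "default_panel",
    "load_panel",
    "save_panel",
]

PROBE_KINDS = (
    "target",
    "reference",
    "q_fragment",
    "d_fragment",
    "x_fragment",
    "y_fragment",
)

#: The 14 pharmacogenes covered by the default panel, in panel order.
PANEL_GENES = (
    "CYP1A1",
    "CYP1A2",
    "CYP1B1",
    "CYP2A6",
    "CYP2B6",
    "CYP2C19",
    "CYP2C9",
    "CYP2D6",
    "CYP2E1",
    "CYP3A4",
    "CYP3A5",
    "GSTM1",
    "GSTP1",
    "GSTT1",
)

#: Gene -> exon regions interrogated by the default panel (40 regions total).
#: Every gene carries at least two probes except GSTT1, whose single-copy
#: status is assessed by one probe in exon 1.
DEFAULT_GRID: dict[str, tuple[str, ...]] = {
    "CYP1A1": ("Exon1", "Exon2", "Exon6"),
    "CYP1A2": ("Exon1", "Exon4", "Exon7"),
    "CYP1B1": ("Exon1", "Exon3"),
    "CYP2A6": ("Exon1", "Exon4", "Exon6", "DownstreamExon9"),
    "CYP2B6": ("Exon1", "Exon5", "Exon9"),
    "CYP2C19": ("Exon1", "Exon5", "Exon9"),
    "CYP2C9": ("Exon1", "Exon3", "Exon5", "Exon9"),
    "CYP2D6": ("Exon1", "Exon2", "Exon6", "Exon9"),
    "CYP2E1": ("Exon1", "Exon5", "Exon8"),
    "CYP3A4": ("Exon1", "Exon7", "Exon13"),
    "CYP3A5": ("Exon1", "Exon5", "Exon10"),
    "GSTM1": ("Exon1", "Exon7"),
    "GSTP1": ("Exon1", "Exon6"),
    "GSTT1": ("Exon1",),
}

_SCHEMA_VERSION = 1

# Control-fragment amplicon lengths follow MLPA convention: Q-fragments are
# the shortest products, D-fragments next, then the X and Y fragments.
_CONTROL_LENGTHS = {
    "q_fragment": (64, 70, 76, 82),
    "d_fragment": (88, 92, 96),
    "x_fragment": (100,),
    "y_fragment": (105,),
}


class PanelError(ValueError):
    """Raised when a panel definition violates a structural invariant."""


@dataclass(frozen=True)
class ProbeDef:
    """One MLPA probe (or control fragment).

    Parameters
    ----------
    probe_id
        Unique identifier within the panel.
    gene
        Gene symbol for target probes; empty string otherwise.
    region
        Exon label for target probes (e.g. ``"Exon1"``), empty otherwise.
    amplicon_length
        Length in nucleotides of the amplified product, 64-504 nt.  Lengths
        identify peaks on the capillary trace; they never enter the dosage
        arithmetic, so only uniqueness matters.
    kind
        One of :data:`PROBE_KINDS`.
    """

    probe_id: str
    gene: str
    region: str
    amplicon_length: int
    kind: str


@dataclass(frozen=True)
class PanelDef:
    """An ordered, validated collection of :class:`ProbeDef`."""

    name: str
    probes: tuple[ProbeDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        _validate(self)

    # -- convenience views -------------------------------------------------

    @property
    def target_probes(self) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.probes if p.kind == "target")

    @property
    def reference_probes(self) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.probes if p.kind == "reference")

    def control_probes(self, kind: str) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.probes if p.kind == kind)

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct target genes, in panel order."""
        seen: dict[str, None] = {}
        for p in self.target_probes:
            seen.setdefault(p.gene, None)
        return tuple(seen)

    def probes_for_gene(self, gene: str) -> tuple[ProbeDef, ...]:
        return tuple(p for p in self.target_probes if p.gene == gene)

    def probe_ids(self, kind: str | None = None) -> tuple[str, ...]:
        return tuple(
            p.probe_id for p in self.probes if kind is None or p.kind == kind
        )


def _validate(panel: PanelDef) -> None:
    seen: set[str] = set()
    for p in panel.probes:
        if p.probe_id in seen:
            raise PanelError(f"duplicate probe_id {p.probe_id!r}")
        seen.add(p.probe_id)
        if p.kind not in PROBE_KINDS:
            raise PanelError(f"probe {p.probe_id!r}: unknown kind {p.kind!r}")
        if p.kind == "target":
            if not p.gene:
                raise PanelError(f"target probe {p.probe_id!r} has empty gene")
            if not p.region:
                raise PanelError(f"target probe {p.probe_id!r} has empty region")
        elif p.gene or p.region:
            raise PanelError(
                f"probe {p.probe_id!r} of kind {p.kind!r} must have empty "
                "gene and region"
            )
        if not (64 <= p.amplicon_length <= 504):
            raise PanelError(
                f"probe {p.probe_id!r}: amplicon_length {p.amplicon_length} "
                "outside [64, 504]"
            )
    if panel.target_probes and not panel.reference_probes:
        raise PanelError("no reference probes")


def default_panel(n_reference: int = 8) -> PanelDef:
    """Build the default 14-gene pharmacogene CNV panel.

    The panel holds 40 target probes laid out per :data:`DEFAULT_GRID`,
    ``n_reference`` reference probes, and the standard MLPA control set
    (4 Q-, 3 D-, 1 X-, 1 Y-fragment).  Amplicon lengths are assigned
    deterministically and uniquely in [128, 504] for targets and
    references; control fragments take conventional short lengths.
    """
    if n_reference < 2:
        raise PanelError("need at least 2 reference probes")
    probes: list[ProbeDef] = []
    lengths = iter(range(128, 505, 8))  # 48 unique lengths, enough for 40+8
    for gene in PANEL_GENES:
        for region in DEFAULT_GRID[gene]:
            probes.append(
                ProbeDef(
                    probe_id=f"{gene}_{region}",
                    gene=gene,
                    region=region,
                    amplicon_length=next(lengths),
                    kind="target",
                )
            )
    for i in range(n_reference):
        probes.append(
            ProbeDef(
                probe_id=f"REF_{i + 1:02d}",
                gene="",
                region="",
                amplicon_length=next(lengths),
                kind="reference",
            )
        )
    for kind, lens in _CONTROL_LENGTHS.items():
        tag = kind[0].upper()
        for i, ln in enumerate(lens):
            pid = f"{tag}{i + 1}" if len(lens) > 1 else f"{tag}F"
            probes.append(
                ProbeDef(probe_id=pid, gene="", region="", amplicon_length=ln, kind=kind)
            )
    return PanelDef(name="pharmacogene-cnv-default", probes=tuple(probes))


def save_panel(panel: PanelDef, path: str | Path) -> None:
    """Write a panel to JSON (schema version 1)."""
    doc = {
        "name": panel.name,
        "schema": _SCHEMA_VERSION,
        "probes": [asdict(p) for p in panel.probes],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_panel(path: str | Path) -> PanelDef:
    """Read a panel from JSON, validating every structural invariant."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PanelError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != _SCHEMA_VERSION:
        raise PanelError(
            f"{path}: unsupported schema {doc.get('schema')!r} "
            f"(expected {_SCHEMA_VERSION})"
        )
    probes = []
    for rec in doc.get("probes", []):
        try:
            probes.append(
                ProbeDef(
                    probe_id=str(rec["probe_id"]),
                    gene=str(rec.get("gene", "")),
                    region=str(rec.get("region", "")),
                    amplicon_length=int(rec["amplicon_length"]),
                    kind=str(rec["kind"]),
                )
            )
        except KeyError as exc:
            raise PanelError(f"{path}: probe record missing field {exc}") from exc
    return PanelDef(name=str(doc.get("name", "unnamed")), probes=tuple(probes))
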