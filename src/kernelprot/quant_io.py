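"""Data model and TSV I/O for reporter-ion quantification tables.

The experimental design this package models is an 8-plex isobaric-tag
(iTRAQ) run: two maize kernel tissues (pericarp, endosperm) sampled at four
developmental stages (10, 20, 33, 46 days after pollination), each labeled
with one reporter channel in the m/z 113-121 range, with a common control
channel (default 113) shared by every sample.  All tables are tab-separated
UTF-8 text with a mandatory header row.

Missing reporter intensities are encoded as *absent cells*, never as zero:
zero is a legal measured intensity and the distinction matters wherever an
intensity lands in a ratio denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: the full 8-plex reporter label set
ITRAQ_CHANNELS = (113, 114, 115, 116, 117, 118, 119, 120, 121)

#: default stage axis, in days after pollination
DEFAULT_STAGES = (10, 20, 33, 46)

KO_PATTERN = re.compile(r"^K\d{5}$")


class Tissue(str, Enum):
    PERICARP = "pericarp"
    ENDOSPERM = "endosperm"


class QuantIOError(ValueError):
    """Raised for malformed or inconsistent quantification inputs."""


@dataclass(frozen=True)
class QuantRecord:
    """One protein's reporter-channel intensities for one tissue/replicate.

    ``intensities`` maps channel (int, member of the configured label set)
    to a non-negative intensity in arbitrary reporter-ion units.  Channels
    that were not measured are simply absent from the map.
    """

    protein_id: str
    tissue: str
    replicate: int
    intensities: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise QuantIOError(f"replicate must be >= 1, got {self.replicate}")
        for ch, v in self.intensities.items():
            if ch not in ITRAQ_CHANNELS:
                raise QuantIOError(f"unknown reporter channel {ch}")
            if v < 0:
                raise QuantIOError(
                    f"negative intensity {v} for {self.protein_id} channel {ch}"
                )

    def key(self) -> tuple[str, str, int]:
        return (self.protein_id, self.tissue, self.replicate)


@dataclass(frozen=True)
class StageDesign:
    """Stage axis plus the tissue -> stage -> reporter-channel assignment.

    The default mirrors the labeling scheme of the modeled experiment:
    pericarp 10/20/33/46 DAP on channels 114-117, endosperm on 118-121,
    control on 113.
    """

    stages: tuple[int, ...] = DEFAULT_STAGES
    channel_map: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: {
            Tissue.PERICARP.value: {10: 114, 20: 115, 33: 116, 46: 117},
            Tissue.ENDOSPERM.value: {10: 118, 20: 119, 33: 120, 46: 121},
        }
    )
    control_channel: int = 113

    def __post_init__(self) -> None:
        if list(self.stages) != sorted(self.stages) or len(set(self.stages)) != len(
            self.stages
        ):
            raise QuantIOError("stages must be strictly increasing in DAP")
        for tissue, m in self.channel_map.items():
            if set(m) != set(self.stages):
                raise QuantIOError(
                    f"channel map for {tissue} must cover exactly the stage list"
                )

    def channel(self, tissue: str, stage: int) -> int:
        return self.channel_map[tissue][stage]


# ---------------------------------------------------------------------------
# annotation / ortholog / pathway / Ct tables
# ---------------------------------------------------------------------------

NAMESPACES = ("GO-BP", "GO-CC", "GO-MF", "COG")


@dataclass
class AnnotationMap:
    """protein_id -> set of (namespace, category label) annotations."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, protein_id: str, namespace: str, category: str) -> None:
        if namespace not in NAMESPACES:
            raise QuantIOError(f"unknown annotation namespace {namespace!r}")
        if not category:
            raise QuantIOError("empty category label")
        self.entries.setdefault(protein_id, set()).add((namespace, category))

    def categories(self, protein_id: str, namespace: str) -> set[str]:
        return {
            cat for ns, cat in self.entries.get(protein_id, set()) if ns == namespace
        }


@dataclass
class OrthologMap:
    """Two-step best-hit mapping: protein -> gene model -> KEGG orthology id."""

    protein_to_gene: dict[str, str] = field(default_factory=dict)
    gene_to_ko: dict[str, str] = field(default_factory=dict)


@dataclass
class PathwayLinkTable:
    """De-duplicated (KO id, pathway id) membership pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def pathways_of(self, ko: str) -> set[str]:
        return {p for k, p in self.pairs if k == ko}

    def members_of(self, pathway: str) -> set[str]:
        return {k for k, p in self.pairs if p == pathway}


@dataclass(frozen=True)
class CtRow:
    """One qPCR measurement: target and reference Ct for a gene/tissue/stage."""

    gene_id: str
    tissue: str
    stage: int
    ct_target: float
    ct_reference: float
    replicate: int = 1


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_quant_table(
    path, channels: Sequence[int] = ITRAQ_CHANNELS
) -> list[QuantRecord]:
    """Read a quantification TSV into :class:`QuantRecord` rows.

    Expected columns: ``protein_id``, ``tissue``, ``replicate``, then one
    column per reporter channel named by its m/z (e.g. ``113``).  Blank
    channel cells become absent channels, not zeros.

    Raises :class:`QuantIOError` on unknown channel columns or duplicate
    (protein, tissue, replicate) keys.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "tissue": str},
        float_precision="round_trip",
    )
    required = {"protein_id", "tissue", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise QuantIOError(f"missing required columns: {sorted(missing)}")
    channel_cols = [c for c in df.columns if c not in required]
    allowed = {str(c) for c in channels}
    for col in channel_cols:
        if col not in allowed:
            raise QuantIOError(f"unknown channel column {col!r}")
    records: list[QuantRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for d in df.to_dict("records"):
        intensities = {}
        for col in channel_cols:
            v = d[col]
            if pd.isna(v):
                continue
            intensities[int(col)] = float(v)
        rec = QuantRecord(
            protein_id=d["protein_id"],
            tissue=d["tissue"],
            replicate=int(d["replicate"]),
            intensities=intensities,
        )
        if rec.key() in seen:
            raise QuantIOError(
                f"duplicate quantification row for protein {rec.protein_id!r} "
                f"({rec.tissue}, replicate {rec.replicate})"
            )
        seen.add(rec.key())
        records.append(rec)
    return records


def write_quant_table(
    records: Iterable[QuantRecord], path, channels: Sequence[int] = ITRAQ_CHANNELS
) -> None:
    """Write records as TSV, fixed column order; absent channels as blanks."""
    rows = []
    for r in sorted(records, key=QuantRecord.key):
        row: dict[str, object] = {
            "protein_id": r.protein_id,
            "tissue": r.tissue,
            "replicate": r.replicate,
        }
        for ch in channels:
            row[str(ch)] = r.intensities.get(ch, None)
        rows.append(row)
    cols = ["protein_id", "tissue", "replicate"] + [str(c) for c in channels]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_annotation_map(path) -> AnnotationMap:
    """Read protein annotations from a 3-column TSV: protein_id, namespace, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    amap = AnnotationMap()
    for row in df.itertuples(index=False):
        amap.add(row.protein_id, row.namespace, row.category)
    return amap


def write_annotation_map(amap: AnnotationMap, path) -> None:
    rows = [
        {"protein_id": pid, "namespace": ns, "category": cat}
        for pid, anns in sorted(amap.entries.items())
        for ns, cat in sorted(anns)
    ]
    pd.DataFrame(rows, columns=["protein_id", "namespace", "category"]).to_csv(
        path, sep="\t", index=False
    )


def read_ortholog_map(path) -> OrthologMap:
    """Read a 3-column TSV: protein_id, gene_model_id, ko_id (ko may be blank)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    omap = OrthologMap()
    for row in df.itertuples(index=False):
        if row.protein_id in omap.protein_to_gene:
            raise QuantIOError(f"multiple gene models for protein {row.protein_id!r}")
        omap.protein_to_gene[row.protein_id] = row.gene_model_id
        ko = getattr(row, "ko_id", None)
        if isinstance(ko, str) and ko:
            omap.gene_to_ko[row.gene_model_id] = ko
    return omap


def write_ortholog_map(omap: OrthologMap, path) -> None:
    rows = [
        {
            "protein_id": pid,
            "gene_model_id": gene,
            "ko_id": omap.gene_to_ko.get(gene, ""),
        }
        for pid, gene in sorted(omap.protein_to_gene.items())
    ]
    pd.DataFrame(rows, columns=["protein_id", "gene_model_id", "ko_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_pathway_links(path, strict: bool = True) -> PathwayLinkTable:
    """Read KO->pathway links in the two-column KEGG REST ``link`` flat format.

    Each non-empty line is ``<ko_id><whitespace><pathway_id>`` (the live
    endpoint prints e.g. ``ko:K01778\tpath:map00460``; a bare ``K01778`` is
    accepted too).  Duplicate pairs collapse.  Under ``strict=True`` a KO id
    not matching ``K#####`` (after stripping an optional ``ko:`` prefix) is a
    parse error naming the offending line; ``strict=False`` admits arbitrary
    synthetic ids.
    """
    table = PathwayLinkTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise QuantIOError(f"line {lineno}: expected two columns, got {line!r}")
            ko, pathway = parts
            if ko.startswith("ko:"):
                ko = ko[3:]
            if strict and not KO_PATTERN.match(ko):
                raise QuantIOError(f"line {lineno}: malformed KO id {ko!r}")
            if not pathway:
                raise QuantIOError(f"line {lineno}: empty pathway id")
            table.pairs.add((ko, pathway))
    return table


def write_pathway_links(table: PathwayLinkTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ko, pathway in sorted(table.pairs):
            fh.write(f"{ko}\t{pathway}\n")


def read_ct_table(path) -> list[CtRow]:
    """Read a qPCR Ct TSV: gene_id, tissue, stage, ct_target, ct_reference, replicate."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "tissue": str},
        float_precision="round_trip",
    )
    rows = []
    for r in df.itertuples(index=False):
        ct_t, ct_r = float(r.ct_target), float(r.ct_reference)
        if not (pd.notna(ct_t) and pd.notna(ct_r)):
            raise QuantIOError(f"non-finite Ct for gene {r.gene_id!r}")
        rows.append(
            CtRow(
                gene_id=r.gene_id,
                tissue=r.tissue,
                stage=int(r.stage),
                ct_target=ct_t,
                ct_reference=ct_r,
                replicate=int(r.replicate),
            )
        )
    return rows


def write_ct_table(rows: Iterable[CtRow], path) -> None:
    recs = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue,
            "stage": r.stage,
            "ct_target": r.ct_target,
            "ct_reference": r.ct_reference,
            "replicate": r.replicate,
        }
        for r in sorted(
            rows, key=lambda r: (r.gene_id, r.tissue, r.stage, r.replicate)
        )
    ]
    pd.DataFrame(
        recs,
        columns=["gene_id", "tissue", "stage", "ct_target", "ct_reference", "replicate"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
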