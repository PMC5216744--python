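"""Tabular I/O for regulation tables, miRNA-target tables, GMT gene sets.

All formats are tab-separated with a header line. Identifier handling is
purely lexical: labels are stripped of surrounding whitespace and internal
whitespace runs are collapsed to single spaces; case is preserved but token
matching (direction, evidence, species) is case-insensitive. Drug
combinations written as a single label (e.g. "5-aza-2'-deoxycytidine +
trichostatin A") stay single molecule nodes.

Malformed data rows are collected and reported together in one
:class:`TableFormatError` (fail-at-end), so a curator sees every bad line of
a file in a single pass instead of one error per run.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

logger = logging.getLogger(__name__)

if TYPE_CHECKING:  # pragma: no cover
    from .nbi_core import ScoreTable

__all__ = [
    "Direction",
    "Evidence",
    "RegulationRecord",
    "TargetRecord",
    "InclusionFilters",
    "TableFormatError",
    "read_sm_mir_table",
    "read_mirna_gene_table",
    "read_gmt",
    "write_sm_mir_table",
    "write_mirna_gene_table",
    "write_predictions",
]


class Direction(enum.Enum):
    """Sign of a small-molecule effect on miRNA expression."""

    UP = "up"
    DOWN = "down"
    UNKNOWN = "unknown"


class Evidence(enum.Enum):
    """Experimental support class for a miRNA-target-gene pair.

    ``strong`` covers low-throughput assays (reporter assay, western blot,
    qPCR); ``weak`` covers high-throughput ones (microarray, CLIP, seq).
    """

    STRONG = "strong"
    WEAK = "weak"


class TableFormatError(ValueError):
    """Raised for structural problems; carries per-row errors when present."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        if self.row_errors:
            detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
            message = f"{message}: {detail}"
        super().__init__(message)


@dataclass(frozen=True)
class RegulationRecord:
    """One curated small-molecule -> miRNA regulation event."""

    molecule_id: str
    mirna_id: str
    direction: Direction
    species_tag: str = ""
    evidence_ref: str = ""

    def __post_init__(self) -> None:
        if not self.molecule_id:
            raise ValueError("empty molecule_id")
        if not self.mirna_id:
            raise ValueError("empty mirna_id")


@dataclass(frozen=True)
class TargetRecord:
    """One curated miRNA -> target-gene pair with its evidence class."""

    mirna_id: str
    gene_id: str
    evidence: Evidence


@dataclass(frozen=True)
class InclusionFilters:
    """Record-level inclusion filters for regulation tables.

    species:
        Keep only rows whose species tag matches this value
        (case-insensitive); ``None`` disables the filter. Rows with an empty
        species tag are kept (absence of a tag is not evidence of another
        species in these curated tables).
    drop_precursors:
        Drop rows whose miRNA label looks like a precursor hairpin rather
        than a mature arm: a lowercase ``mir-`` stem with no ``-3p``/``-5p``
        suffix (miRBase writes mature IDs with a capital R, ``miR-``).
    """

    species: str | None = None
    drop_precursors: bool = False


_WS = re.compile(r"\s+")
_PRECURSOR = re.compile(r"(?:^|-)mir-\d")
_MATURE_ARM = re.compile(r"-[35]p$", re.IGNORECASE)


def _clean(label: str) -> str:
    return _WS.sub(" ", label.strip())


def _is_precursor_label(mirna_id: str) -> bool:
    return bool(_PRECURSOR.search(mirna_id)) and not _MATURE_ARM.search(mirna_id)


def _header_index(header: list[str], wanted: dict[str, list[str]], path: Path) -> dict[str, int]:
    """Map logical column names to positions, accepting listed synonyms."""
    lowered = [h.strip().lower() for h in header]
    index: dict[str, int] = {}
    for logical, names in wanted.items():
        for name in names:
            if name in lowered:
                index[logical] = lowered.index(name)
                break
    return index


def read_sm_mir_table(
    path: str | Path,
    filters: InclusionFilters | None = None,
) -> list[RegulationRecord]:
    """Read a regulation TSV (columns molecule, mirna, direction[, species, reference]).

    Rows failing a filter are silently dropped; rows with an unparseable
    direction token are collected and reported together with line numbers in
    a single :class:`TableFormatError`. Row order is preserved.
    """
    path = Path(path)
    filters = filters or InclusionFilters()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = _header_index(
            header,
            {
                "molecule": ["molecule", "small_molecule", "sm", "drug"],
                "mirna": ["mirna", "mir", "microrna"],
                "direction": ["direction", "regulation"],
                "species": ["species", "organism"],
                "reference": ["reference", "ref", "pmid"],
            },
            path,
        )
        for required in ("molecule", "mirna", "direction"):
            if required not in cols:
                raise TableFormatError(f"{path}: missing required column {required!r}")

        records: list[RegulationRecord] = []
        row_errors: list[tuple[int, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")

            def get(col: str) -> str:
                idx = cols.get(col)
                return _clean(fields[idx]) if idx is not None and idx < len(fields) else ""

            molecule, mirna = get("molecule"), get("mirna")
            token = get("direction").lower()
            if not molecule or not mirna:
                row_errors.append((lineno, "empty molecule or miRNA label"))
                continue
            try:
                direction = Direction(token)
            except ValueError:
                row_errors.append((lineno, f"unknown direction token {token!r}"))
                continue

            species = get("species")
            if filters.species is not None and species and species.lower() != filters.species.lower():
                continue
            if filters.drop_precursors and _is_precursor_label(mirna):
                continue
            records.append(
                RegulationRecord(molecule, mirna, direction, species, get("reference"))
            )

    if row_errors:
        raise TableFormatError(f"{path}: malformed rows", row_errors)
    return records


def read_mirna_gene_table(path: str | Path) -> list[TargetRecord]:
    """Read a miRNA-target TSV (columns mirna, gene, evidence), in file order."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = _header_index(
            header,
            {
                "mirna": ["mirna", "mir", "microrna"],
                "gene": ["gene", "target", "target_gene"],
                "evidence": ["evidence", "support", "validation"],
            },
            path,
        )
        for required in ("mirna", "gene", "evidence"):
            if required not in cols:
                raise TableFormatError(f"{path}: missing required column {required!r}")

        records: list[TargetRecord] = []
        row_errors: list[tuple[int, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                mirna = _clean(fields[cols["mirna"]])
                gene = _clean(fields[cols["gene"]])
                token = _clean(fields[cols["evidence"]]).lower()
            except IndexError:
                row_errors.append((lineno, "too few fields"))
                continue
            try:
                evidence = Evidence(token)
            except ValueError:
                row_errors.append((lineno, f"unknown evidence token {token!r}"))
                continue
            records.append(TargetRecord(mirna, gene, evidence))

    if row_errors:
        raise TableFormatError(f"{path}: malformed rows", row_errors)
    return records


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name, description, then one or more gene labels per line.

    Duplicate genes within a line are collapsed; a duplicated set name is
    overwritten by the later line with a logged warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    row_errors: list[tuple[int, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                row_errors.append((lineno, f"expected >=3 tab-separated fields, got {len(fields)}"))
                continue
            name = _clean(fields[0])
            genes = {_clean(g) for g in fields[2:] if g.strip()}
            if name in sets:
                logger.warning("%s:%d: duplicate gene-set name %r, last definition wins", path, lineno, name)
            sets[name] = genes
    if row_errors:
        raise TableFormatError(f"{path}: malformed GMT lines", row_errors)
    return sets


def write_sm_mir_table(records: list[RegulationRecord], path: str | Path) -> None:
    """Write regulation records as a TSV readable by :func:`read_sm_mir_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("molecule\tmirna\tdirection\tspecies\treference\n")
        for r in records:
            fh.write(
                f"{r.molecule_id}\t{r.mirna_id}\t{r.direction.value}\t"
                f"{r.species_tag}\t{r.evidence_ref}\n"
            )


def write_mirna_gene_table(records: list[TargetRecord], path: str | Path) -> None:
    """Write target records as a TSV readable by :func:`read_mirna_gene_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("mirna\tgene\tevidence\n")
        for r in records:
            fh.write(f"{r.mirna_id}\t{r.gene_id}\t{r.evidence.value}\n")


def write_predictions(table: "ScoreTable", path: str | Path) -> None:
    """Write a score table as a deterministic TSV.

    Columns: query_id, candidate_id, raw_score, std_score, known_link (0/1),
    rank. Rows sorted by rank with known links (rank 0) first; ties within a
    rank class broken by candidate label. Byte output is a pure function of
    the table contents.
    """
    path = Path(path)
    rows = sorted(table.candidates, key=lambda c: (c.rank, c.candidate_id))
    with path.open("w", newline="") as fh:
        fh.write("query_id\tcandidate_id\traw_score\tstd_score\tknown_link\trank\n")
        for c in rows:
            fh.write(
                f"{table.query_id}\t{c.candidate_id}\t{c.raw_score:.10g}\t"
                f"{c.std_score:.10g}\t{int(c.known_link)}\t{c.rank}\n"
            )
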