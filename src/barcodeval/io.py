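"""Per-locus alignment and specimen-manifest I/O, dataset assembly.

A study dataset is a set of specimens, each with a species label and a
binary sequencing outcome per locus, plus one pre-aligned FASTA per locus
containing rows for exactly the specimens that sequenced successfully.
Single-, two- and three-locus barcodes are assembled by concatenating
aligned loci over the specimens sequenced at all of them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = set("ACGT-N")

#: Species encoded in specimen-ID prefixes (underscore-delimited), the
#: convention used for the six pine-moth species this toolkit emulates.
DEFAULT_PREFIX_TABLE: Mapping[str, str] = {
    "MW": "D. punctatus",
    "SM": "D. kikuchii",
    "YN": "D. houi",
    "YS": "D. spectabilis",
    "CS": "D. superans",
    "LY": "D. tabulaeformis",
}


class FormatError(ValueError):
    """Malformed input: ragged alignment rows, bad manifest columns."""


class LabelingError(ValueError):
    """A specimen ID could not be resolved to a species label."""


class InputError(ValueError):
    """Empty or otherwise unusable input."""


@dataclass
class SpecimenRecord:
    """One specimen: its species label, optional site, and per-locus outcome.

    ``locus_status`` maps locus name to True (sequenced) / False (failed).
    """

    specimen_id: str
    species_label: str
    site_id: str | None = None
    locus_status: dict[str, bool] = field(default_factory=dict)


@dataclass
class LocusAlignment:
    """A pre-aligned locus: equal-length rows keyed by specimen ID."""

    locus_name: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError(f"alignment {self.locus_name!r} has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment {self.locus_name!r}: row lengths {sorted(lengths)}"
            )
        if 0 in lengths:
            raise InputError(f"alignment {self.locus_name!r} has zero-length rows")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate specimen IDs in {self.locus_name!r}")
        cleaned = []
        for sid, seq in self.rows:
            seq = seq.upper()
            bad = set(seq) - ALPHABET
            if bad:
                logger.warning(
                    "locus %s, specimen %s: mapping non-standard characters %s to N",
                    self.locus_name, sid, sorted(bad),
                )
                seq = re.sub(f"[{''.join(re.escape(c) for c in sorted(bad))}]", "N", seq)
            cleaned.append((sid, seq))
        self.rows = cleaned

    @property
    def sequence_length(self) -> int:
        return len(self.rows[0][1])

    @property
    def specimen_ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def sequence_of(self, specimen_id: str) -> str:
        for sid, seq in self.rows:
            if sid == specimen_id:
                return seq
        raise KeyError(specimen_id)


@dataclass
class MultiLocusDataset:
    """Specimens x loci container with labels and per-locus availability."""

    specimens: list[SpecimenRecord]
    loci: dict[str, LocusAlignment]

    def __post_init__(self) -> None:
        if not self.loci:
            raise InputError("dataset must contain at least one locus")
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate specimen IDs in manifest")
        by_id = {s.specimen_id: s for s in self.specimens}
        for name, aln in self.loci.items():
            present = set(aln.specimen_ids)
            for spec in self.specimens:
                status = spec.locus_status.get(name, False)
                if status and spec.specimen_id not in present:
                    raise FormatError(
                        f"{spec.specimen_id} marked sequenced at {name} but has no row"
                    )
                if not status and spec.specimen_id in present:
                    raise FormatError(
                        f"{spec.specimen_id} has a row at {name} but is marked failed"
                    )
            unknown = present - set(by_id)
            if unknown:
                raise LabelingError(
                    f"alignment {name} contains specimens absent from manifest: {sorted(unknown)[:5]}"
                )

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def species_of(self, specimen_id: str) -> str:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s.species_label
        raise KeyError(specimen_id)

    def labels_for(self, specimen_ids: Iterable[str]) -> list[str]:
        by_id = {s.specimen_id: s.species_label for s in self.specimens}
        return [by_id[i] for i in specimen_ids]


def _resolve_species(record_id: str, species_map) -> str:
    """Resolve a FASTA record ID to a species label.

    ``species_map`` is either an explicit mapping from full IDs, or the
    string ``"prefix"`` to apply the underscore-delimited prefix rule with
    :data:`DEFAULT_PREFIX_TABLE`, or a mapping of prefixes when used with
    IDs of the form ``PREFIX..._...`` / ``PREFIXnn``.
    """
    if callable(species_map):
        label = species_map(record_id)
        if label is None:
            raise LabelingError(f"cannot resolve species for {record_id!r}")
        return label
    if isinstance(species_map, Mapping) and record_id in species_map:
        return species_map[record_id]
    table = DEFAULT_PREFIX_TABLE if species_map in (None, "prefix") else species_map
    if isinstance(table, Mapping):
        head = record_id.split("_")[0]
        for prefix, label in table.items():
            if head.startswith(prefix):
                return label
    raise LabelingError(f"cannot resolve species for {record_id!r}")


def read_alignment(path, locus_name: str, species_map="prefix") -> tuple[LocusAlignment, dict[str, str]]:
    """Read a pre-aligned FASTA into a :class:`LocusAlignment`.

    Returns the alignment and a mapping specimen_id -> species label
    resolved via ``species_map`` (an explicit dict keyed by record ID, a
    prefix table, the string ``"prefix"`` for the default table, or a
    callable). Record order is preserved; sequences are uppercased and
    non-standard characters mapped to N.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    rows = [(r.id, str(r.seq)) for r in records]
    labels = {rid: _resolve_species(rid, species_map) for rid, _ in rows}
    return LocusAlignment(locus_name=locus_name, rows=rows), labels


def write_alignment(alignment: LocusAlignment, path) -> None:
    """Write an alignment as FASTA, preserving row order."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_manifest(path, locus_names: Sequence[str] | None = None) -> list[SpecimenRecord]:
    """Read a TSV manifest: specimen_id, species, site, then one 0/1 column per locus."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"specimen_id", "species", "site"}
    if not required <= set(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    loci = [c for c in df.columns if c not in required]
    if locus_names is not None:
        missing = set(locus_names) - set(loci)
        if missing:
            raise FormatError(f"manifest lacks locus columns {sorted(missing)}")
        loci = list(locus_names)
    out = []
    for _, row in df.iterrows():
        status = {l: row[l] in ("1", "True", "true") for l in loci}
        site = row["site"] if isinstance(row["site"], str) and row["site"] else None
        out.append(SpecimenRecord(row["specimen_id"], row["species"], site, status))
    return out


def write_manifest(specimens: Sequence[SpecimenRecord], path, locus_names: Sequence[str]) -> None:
    import pandas as pd

    rows = []
    for s in specimens:
        row = {
            "specimen_id": s.specimen_id,
            "species": s.species_label,
            "site": s.site_id or "",
        }
        for l in locus_names:
            row[l] = int(bool(s.locus_status.get(l, False)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def concatenate(
    dataset: MultiLocusDataset,
    loci: Sequence[str],
    missing_policy: str = "intersect",
) -> LocusAlignment:
    """Assemble a (possibly multi-locus) barcode alignment.

    Under ``intersect`` (default) rows are the specimens sequenced at ALL
    named loci; under ``pad`` every specimen sequenced at any named locus
    is kept, with missing loci filled with N. Concatenated length is the
    sum of locus lengths. A single-locus list returns that alignment.
    """
    if not loci:
        raise InputError("empty locus list")
    for name in loci:
        if name not in dataset.loci:
            raise InputError(f"unknown locus {name!r}")
    if len(loci) == 1:
        return dataset.loci[loci[0]]
    if missing_policy not in ("intersect", "pad"):
        raise InputError(f"unknown missing_policy {missing_policy!r}")

    per_locus_ids = [set(dataset.loci[l].specimen_ids) for l in loci]
    if missing_policy == "intersect":
        keep = set.intersection(*per_locus_ids)
    else:
        keep = set.union(*per_locus_ids)
    # preserve manifest order
    ordered = [s.specimen_id for s in dataset.specimens if s.specimen_id in keep]
    if not ordered:
        raise InputError(f"no specimen sequenced at all of {list(loci)}")

    seq_maps = [dict(dataset.loci[l].rows) for l in loci]
    lengths = [dataset.loci[l].sequence_length for l in loci]
    rows = []
    for sid in ordered:
        parts = []
        for m, L in zip(seq_maps, lengths):
            parts.append(m.get(sid, "N" * L))
        rows.append((sid, "".join(parts)))
    return LocusAlignment(locus_name="+".join(loci), rows=rows)


def sequencing_success(
    dataset: MultiLocusDataset, loci: Sequence[str]
) -> tuple[float, int, int]:
    """Fraction of specimens sequenced at ALL listed loci.

    Returns ``(rate, n_success, n_submitted)`` where rate is in [0, 1].
    For a multi-locus barcode the joint count is used: a specimen counts
    as a success only if every listed locus sequenced.
    """
    if not loci:
        raise InputError("empty locus list")
    for name in loci:
        if name not in dataset.loci:
            raise InputError(f"unknown locus {name!r}")
    n_submitted = len(dataset.specimens)
    if n_submitted == 0:
        raise InputError("no specimens in dataset")
    n_success = sum(
        1
        for s in dataset.specimens
        if all(s.locus_status.get(l, False) for l in loci)
    )
    return n_success / n_submitted, n_success, n_submitted
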