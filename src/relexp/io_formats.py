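"""Readers and writers for expression tables and gene-set collections.

Three text formats are supported, each optionally gzip-compressed:

* **CSV** expression tables — genes in rows, samples in columns, first
  column the gene identifier, mandatory header row, period decimal
  separator.
* **GEO SOFT (GDS)** curated dataset files — the layout with ``^SUBSET``
  blocks tagging samples with cohort labels and a
  ``!dataset_table_begin`` / ``!dataset_table_end`` delimited table.
  Subset descriptions become a :class:`CohortMap`, which drives
  cohort-based class assignment.
* **GMT** gene-set files — one tab-separated line per set: name,
  description, then one or more gene symbols.

Multiple datasets are merged by exact gene-identifier intersection
(samples concatenated, labels carried through).  Blank or non-numeric
expression cells are parse errors, never imputed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import CLASS_1, CLASS_2, DataError, ExpressionDataset


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class CohortMap:
    """Cohort tag -> sample ids, parsed from SOFT subset blocks.

    A sample may carry several tags (e.g. both a disease-state and an
    age cohort).
    """

    cohorts: dict[str, list[str]] = field(default_factory=dict)

    def tags(self) -> list[str]:
        return list(self.cohorts)

    def samples(self, tag: str) -> list[str]:
        try:
            return self.cohorts[tag]
        except KeyError:
            raise KeyError(f"unknown cohort tag {tag!r}") from None


@dataclass
class GeneSet:
    name: str
    description: str
    gene_ids: list[str]


@dataclass
class GeneSetCollection:
    """Ordered, name-unique collection of gene sets ("gene network file")."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(f"unknown gene set {name!r}")


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# CSV expression tables


def read_csv_expression(path) -> ExpressionDataset:
    """Read a CSV expression table; all samples start unassigned.

    Dialect: header ``gene_id,<sample1>,...``; each following row a gene
    identifier and one numeric value per sample.  Ragged rows, duplicate
    identifiers and non-numeric cells raise :class:`ParseError` naming
    the offending line.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file", line=1)
    header = lines[0].split(",")
    if len(header) < 2:
        raise ParseError("header must name at least one sample", line=1)
    sample_ids = [h.strip() for h in header[1:]]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(parts)}", line=lineno
            )
        gene_ids.append(parts[0].strip())
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError:
            bad = next(x for x in parts[1:] if not _is_number(x))
            raise ParseError(f"non-numeric expression value {bad.strip()!r}", line=lineno)
    if not rows:
        raise ParseError("no data rows", line=1)
    if len(set(gene_ids)) != len(gene_ids):
        raise ParseError("duplicate gene identifier")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError("duplicate sample identifier", line=1)
    return ExpressionDataset(gene_ids, sample_ids, np.array(rows, dtype=float))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_csv_expression(dataset: ExpressionDataset, path) -> None:
    """Write a dataset in the CSV dialect of :func:`read_csv_expression`.

    Values are written with ``repr`` so the read-back is bit-exact.
    """
    with _open_text(path, "wt") as fh:
        fh.write("gene_id," + ",".join(dataset.sample_ids) + "\n")
        for i, g in enumerate(dataset.gene_ids):
            fh.write(g + "," + ",".join(repr(float(v)) for v in dataset.values[i]) + "\n")


# ---------------------------------------------------------------------------
# GEO SOFT (GDS layout)


def read_soft(path) -> tuple[ExpressionDataset, CohortMap]:
    """Read a GDS-layout SOFT file: expression table plus cohort map.

    Subset blocks (``^SUBSET`` / ``!subset_description`` /
    ``!subset_sample_id``) become cohort tags.  The dataset table's first
    column is the probe/gene identifier; an ``IDENTIFIER`` annotation
    column, if present, is skipped; remaining columns are samples.
    Classes are left unassigned.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()

    cohorts: dict[str, list[str]] = {}
    table_start = None
    table_end = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("^SUBSET"):
            desc = None
            members: list[str] | None = None
            j = i + 1
            while j < len(lines) and not lines[j].startswith("^") and not lines[j].startswith("!dataset_table_begin"):
                if lines[j].startswith("!subset_description"):
                    desc = lines[j].split("=", 1)[1].strip()
                elif lines[j].startswith("!subset_sample_id"):
                    members = [s.strip() for s in lines[j].split("=", 1)[1].split(",") if s.strip()]
                j += 1
            if desc is None or members is None:
                raise ParseError("subset block missing description or sample ids", line=i + 1)
            cohorts.setdefault(desc, [])
            for m in members:
                if m not in cohorts[desc]:
                    cohorts[desc].append(m)
            i = j
            continue
        if line.startswith("!dataset_table_begin"):
            table_start = i + 1
        elif line.startswith("!dataset_table_end"):
            table_end = i
        i += 1

    if table_start is None or table_end is None or table_end <= table_start:
        raise ParseError("missing !dataset_table_begin/!dataset_table_end delimiters")

    header = lines[table_start].split("\t")
    if len(header) < 2:
        raise ParseError("dataset table header has no sample columns", line=table_start + 1)
    first_data_col = 1
    if len(header) > 2 and header[1].strip().upper() == "IDENTIFIER":
        first_data_col = 2
    sample_ids = [h.strip() for h in header[first_data_col:]]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno0 in range(table_start + 1, table_end):
        line = lines[lineno0]
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(parts)}", line=lineno0 + 1
            )
        gene_ids.append(parts[0].strip())
        cells = parts[first_data_col:]
        for c in cells:
            if not _is_number(c):
                raise ParseError(f"non-numeric expression value {c.strip()!r}", line=lineno0 + 1)
        rows.append([float(c) for c in cells])
    if not rows:
        raise ParseError("dataset table contains no data rows")

    dataset = ExpressionDataset(gene_ids, sample_ids, np.array(rows, dtype=float))
    known = set(sample_ids)
    for tag, members in cohorts.items():
        for m in members:
            if m not in known:
                raise ParseError(f"subset {tag!r} references unknown sample {m!r}")
    return dataset, CohortMap(cohorts)


def write_soft(
    dataset: ExpressionDataset,
    cohorts: CohortMap,
    path,
    dataset_id: str = "GDS0000",
) -> None:
    """Write a minimal GDS-layout SOFT file (fixture/export use)."""
    with _open_text(path, "wt") as fh:
        fh.write(f"^DATASET = {dataset_id}\n")
        fh.write("!dataset_title = relexp export\n")
        for k, (tag, members) in enumerate(cohorts.cohorts.items(), start=1):
            fh.write(f"^SUBSET = {dataset_id}_{k}\n")
            fh.write(f"!subset_description = {tag}\n")
            fh.write("!subset_sample_id = " + ",".join(members) + "\n")
            fh.write("!subset_type = cohort\n")
        fh.write("!dataset_table_begin\n")
        fh.write("ID_REF\t" + "\t".join(dataset.sample_ids) + "\n")
        for i, g in enumerate(dataset.gene_ids):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in dataset.values[i]) + "\n")
        fh.write("!dataset_table_end\n")


def assign_classes_by_cohort(
    dataset: ExpressionDataset,
    cohorts: CohortMap,
    class1_tags: Sequence[str],
    class2_tags: Sequence[str],
) -> ExpressionDataset:
    """Assign class labels from cohort tags; untagged samples stay out.

    All samples under any of ``class1_tags`` go to class 1 and likewise
    for class 2; a sample claimed by both sides is a conflict error.
    """
    if not class1_tags or not class2_tags:
        raise DataError("both class tag lists must be non-empty")
    c1: list[str] = []
    c2: list[str] = []
    for tag in class1_tags:
        c1.extend(cohorts.samples(tag))
    for tag in class2_tags:
        c2.extend(cohorts.samples(tag))
    overlap = sorted(set(c1) & set(c2))
    if overlap:
        raise DataError(f"samples claimed by both classes: {', '.join(overlap)}")
    labels = {s: CLASS_1 for s in c1}
    labels.update({s: CLASS_2 for s in c2})
    return dataset.with_classes(labels)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...).

    Duplicate symbols within a line are dropped keeping the first
    occurrence; a line with fewer than three fields is a parse error.
    """
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description and >=1 gene", line=lineno)
            name, desc = parts[0], parts[1]
            if name in seen_names:
                raise ParseError(f"duplicate gene set name {name!r}", line=lineno)
            seen_names.add(name)
            genes: list[str] = []
            for g in parts[2:]:
                g = g.strip()
                if g and g not in genes:
                    genes.append(g)
            if not genes:
                raise ParseError("gene set has no genes", line=lineno)
            sets.append(GeneSet(name, desc, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with _open_text(path, "wt") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.gene_ids]) + "\n")


# ---------------------------------------------------------------------------
# Merging


def merge_datasets(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Merge datasets on the intersection of their gene identifiers.

    The merged gene set keeps the first dataset's gene order; samples
    are concatenated in input order and class labels carried through.
    Probe identifiers are matched exactly (no cross-platform mapping,
    no collapsing of probes to symbols).
    """
    if len(datasets) < 2:
        raise DataError("merge requires at least two datasets")
    common = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        common &= set(d.gene_ids)
    genes = [g for g in datasets[0].gene_ids if g in common]
    if not genes:
        raise DataError("gene identifier intersection is empty; nothing to merge")
    all_samples: list[str] = []
    for d in datasets:
        all_samples.extend(d.sample_ids)
    dup = {s for s in all_samples if all_samples.count(s) > 1}
    if dup:
        raise DataError(f"duplicate sample ids across inputs: {', '.join(sorted(dup))}")
    blocks = []
    labels: dict[str, int] = {}
    for d in datasets:
        idx = [d.gene_index(g) for g in genes]
        blocks.append(d.values[idx, :])
        labels.update(d.class_of)
    return ExpressionDataset(genes, all_samples, np.concatenate(blocks, axis=1), labels)
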