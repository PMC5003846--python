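"""Readers and writers for panel counts, expression matrices and RCC files.

Supported on-disk forms
-----------------------
* RCC — the per-sample text export of an nCounter-style instrument: sections
  delimited by ``<Name>`` / ``</Name>`` lines, with a ``Code_Summary`` CSV
  table of (CodeClass, Name, Accession, Count).  Other dialects are rejected.
* TSV count table — columns ``gene``, ``probe_class``, then one column per
  sample; paired with a sample-annotation TSV (``sample_id``, ``condition``,
  ``cell_line``).
* TSV expression matrix — ``gene`` column plus sample columns, log2 scale,
  empty cells denoting missing values.

Floats are written at six decimal places, so write/read round-trips are exact
at that precision; counts round-trip bit-identically.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FormatError, PanelRun

_SECTION_RE = re.compile(r"^<(/?)([A-Za-z_]+)>\s*$")

# CodeClass normalisation: multi-codeset panels suffix Endogenous with a digit.
_CLASS_MAP = {
    "negative": "negative",
    "positive": "positive",
    "housekeeping": "housekeeping",
}


def _map_code_class(raw: str) -> str:
    low = raw.strip().lower()
    if re.fullmatch(r"endogenous\d*", low):
        return "endogenous"
    if low in _CLASS_MAP:
        return _CLASS_MAP[low]
    raise FormatError(f"unknown CodeClass '{raw.strip()}'")


@dataclass
class RccSample:
    """One sample's worth of panel counts, as parsed from a single RCC file."""

    sample_id: str
    counts: pd.Series
    probe_class: pd.Series
    header: dict = field(default_factory=dict)
    lane: dict = field(default_factory=dict)


def read_rcc(path: str | Path) -> RccSample:
    """Parse a single RCC file into an :class:`RccSample` fragment.

    Raises :class:`~cocount.containers.FormatError` on a missing or empty
    ``Code_Summary`` section, a non-integer count, or an unknown CodeClass.
    """
    path = Path(path)
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in path.read_text().splitlines():
        m = _SECTION_RE.match(line.strip())
        if m:
            closing, name = m.group(1) == "/", m.group(2)
            if closing:
                if name != current:
                    raise FormatError(f"mismatched section tag </{name}> in {path.name}")
                current = None
            else:
                current = name
                sections.setdefault(name, [])
            continue
        if current is not None and line.strip():
            sections[current].append(line)

    for required in ("Header", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise FormatError(f"RCC file {path.name} lacks a {required} section")

    def _kv(lines: list[str]) -> dict:
        out = {}
        for row in csv.reader(lines):
            if len(row) >= 2:
                out[row[0].strip()] = row[1].strip()
        return out

    header = _kv(sections["Header"])
    lane = _kv(sections["Lane_Attributes"])

    rows = list(csv.reader(sections["Code_Summary"]))
    if rows and [c.strip().lower() for c in rows[0][:2]] == ["codeclass", "name"]:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"empty Code_Summary in {path.name}")

    names: list[str] = []
    classes: list[str] = []
    counts: list[int] = []
    for row in rows:
        if len(row) != 4:
            raise FormatError(
                f"Code_Summary row in {path.name} does not have 4 fields: {row!r}"
            )
        code_class, name, _accession, count = (c.strip() for c in row)
        try:
            value = int(count)
        except ValueError:
            raise FormatError(
                f"non-integer count '{count}' for probe {name} in {path.name}"
            ) from None
        names.append(name)
        classes.append(_map_code_class(code_class))
        counts.append(value)

    index = pd.Index(names, name="gene")
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probes in {path.name}: {dups}")
    sample_id = lane.get("ID") or path.stem
    return RccSample(
        sample_id=sample_id,
        counts=pd.Series(counts, index=index, dtype=np.int64),
        probe_class=pd.Series(classes, index=index),
        header=header,
        lane=lane,
    )


def merge_runs(
    fragments: list[RccSample], annotations: pd.DataFrame | None = None
) -> PanelRun:
    """Assemble single-sample RCC fragments into one :class:`PanelRun`.

    All fragments must carry the identical probe list (same codeset); a
    mismatch raises an error listing the symmetric difference of gene sets.
    ``annotations`` is indexed by sample id with columns ``condition`` and
    ``cell_line``; when omitted, both are set to ``"unspecified"``.
    """
    if not fragments:
        raise FormatError("no RCC fragments to merge")
    ref = fragments[0]
    for frag in fragments[1:]:
        if not ref.counts.index.equals(frag.counts.index):
            diff = sorted(
                set(ref.counts.index).symmetric_difference(frag.counts.index)
            )
            raise FormatError(
                f"probe sets differ between {ref.sample_id} and {frag.sample_id}; "
                f"symmetric difference: {diff}"
            )
        if not ref.probe_class.equals(frag.probe_class.loc[ref.probe_class.index]):
            raise FormatError(
                f"probe classes differ between {ref.sample_id} and {frag.sample_id}"
            )
    ids = [f.sample_id for f in fragments]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate sample ids across RCC files: {ids}")
    counts = pd.concat({f.sample_id: f.counts for f in fragments}, axis=1)
    counts = counts[ids]
    if annotations is None:
        annotations = pd.DataFrame(
            {"condition": "unspecified", "cell_line": "unspecified"}, index=ids
        )
    return PanelRun(counts=counts, probe_class=ref.probe_class.copy(), samples=annotations)


def read_rcc_dir(directory: str | Path, annotations: pd.DataFrame | None = None) -> PanelRun:
    """Read every ``*.RCC`` / ``*.rcc`` file in a directory and merge them."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".rcc")
    if not paths:
        raise FormatError(f"no RCC files found in {directory}")
    return merge_runs([read_rcc(p) for p in paths], annotations)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns:
        raise FormatError("annotation table lacks a 'sample_id' column")
    return table.set_index("sample_id")


def write_annotations(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, annotations_path: str | Path) -> PanelRun:
    """Read a TSV count table plus its sample-annotation TSV into a PanelRun."""
    table = pd.read_csv(path, sep="\t")
    for col in ("gene", "probe_class"):
        if col not in table.columns:
            raise FormatError(f"count table lacks a '{col}' column")
    gene = table["gene"].astype(str)
    if gene.duplicated().any():
        dups = gene[gene.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene names: {dups}")
    sample_cols = [c for c in table.columns if c not in ("gene", "probe_class")]
    counts = table[sample_cols].copy()
    counts.index = pd.Index(gene, name="gene")
    arr = counts.to_numpy()
    if not np.isfinite(arr.astype(float)).all() or not np.array_equal(
        arr.astype(float), np.floor(arr.astype(float))
    ):
        raise FormatError("non-integer count in count table")
    probe_class = pd.Series(table["probe_class"].astype(str).to_numpy(), index=counts.index)
    samples = read_annotations(annotations_path)
    return PanelRun(counts=counts, probe_class=probe_class, samples=samples)


def write_count_table(run: PanelRun, path: str | Path, annotations_path: str | Path) -> None:
    out = run.counts.copy()
    out.insert(0, "probe_class", run.probe_class)
    out.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)
    write_annotations(run.samples, annotations_path)


def read_expression_matrix(
    path: str | Path, annotations_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a log2 expression TSV (empty cells = missing) and its annotations."""
    table = pd.read_csv(path, sep="\t")
    if "gene" not in table.columns:
        raise FormatError("expression matrix lacks a 'gene' column")
    gene = table["gene"].astype(str)
    values = table.drop(columns=["gene"]).astype(float)
    values.index = pd.Index(gene, name="gene")
    samples = read_annotations(annotations_path) if annotations_path else None
    return ExpressionMatrix(values=values, samples=samples)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, annotations_path: str | Path | None = None
) -> None:
    expr.values.rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    if annotations_path:
        write_annotations(expr.samples, annotations_path)


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    """Write any genes x samples float matrix as TSV at 6 decimal places."""
    values.rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
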