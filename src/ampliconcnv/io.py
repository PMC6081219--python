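"""Readers and writers for amplicon-panel coverage data.

Two plain-text inputs drive the whole analysis:

* the **design BED** produced by the panel designer — one line per amplicon,
  with an attribute column carrying the multiplex primer-pool assignment
  (``Pool=<int>``, key matched case-insensitively) and usually a gene label
  (``GENE_ID=<name>``);
* the **barcode/amplicon coverage matrix** emitted by the coverage-analysis
  step — a tab-separated table of raw read depths, amplicons x samples.
  Two header dialects are accepted: ``amplicon_id<TAB><barcodes...>`` and
  ``Gene<TAB>Target<TAB><barcodes...>`` (amplicon ids taken from *Target*).

BED coordinates are kept 0-based half-open in memory; report-style outputs
(the calls table) convert to 1-based inclusive, as in clinical reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["chrom", "start", "end", "gene", "pool"]

#: Column order of the calls table written by :func:`write_calls`.
CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "gene",
    "first_amplicon",
    "last_amplicon",
    "n_amplicons",
    "start",
    "end",
    "copy_state",
    "mean_norm_depth",
    "sd_flag",
    "t_p_value",
]

SEX_VALUES = {"male", "female", "unknown"}


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1..chr22, chrX, chrY, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    if c.upper() == "X":
        return (0, 23, "")
    if c.upper() == "Y":
        return (0, 24, "")
    return (1, 0, chrom)


@dataclass
class AmpliconDataset:
    """Joined, validated design + coverage data, sorted in genomic order.

    Attributes
    ----------
    design : pandas.DataFrame
        Indexed by ``amplicon_id``; columns chrom, start, end, gene, pool.
    depths : pandas.DataFrame
        Raw read depths, same row index/order as ``design``; one column per
        sample (barcode).
    meta : pandas.DataFrame or None
        Optional per-sample metadata (column ``sex``), indexed by sample id.
    """

    design: pd.DataFrame
    depths: pd.DataFrame
    meta: pd.DataFrame | None = None
    orphans_design: list = field(default_factory=list)
    orphans_matrix: list = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.depths.columns)

    @property
    def pool_sizes(self) -> pd.Series:
        """Number of amplicons per primer pool (m, n, ... in pool order)."""
        return self.design["pool"].value_counts().sort_index()

    def sex_of(self, sample_id: str) -> str:
        if self.meta is None or sample_id not in self.meta.index:
            return "unknown"
        return self.meta.loc[sample_id, "sex"]


def _parse_attributes(fields: list[str]) -> dict[str, str]:
    """Collect key=value pairs from any ';'-separated attribute fields."""
    attrs: dict[str, str] = {}
    for f in fields:
        if "=" not in f:
            continue
        for item in f.split(";"):
            if "=" in item:
                key, _, val = item.partition("=")
                attrs.setdefault(key.strip().lower(), val.strip())
    return attrs


def read_design_bed(path: str | Path) -> pd.DataFrame:
    """Parse an amplicon design BED into a design table.

    Requires a ``Pool=<int>`` attribute on every data line (the key is
    matched case-insensitively); a ``GENE_ID=`` / ``GENE=`` attribute
    supplies the gene label when present. A leading ``track`` line is
    skipped. Raises ``ValueError`` naming the offending line on a missing
    pool attribute or non-integer coordinates.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=4 tab-separated BED fields"
                )
            chrom, start_s, end_s, amplicon_id = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start must be < end ({start} >= {end})"
                )
            attrs = _parse_attributes(fields[4:])
            if "pool" not in attrs:
                raise ValueError(
                    f"{path}: line {lineno}: missing Pool=<int> attribute"
                )
            try:
                pool = int(attrs["pool"])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer pool {attrs['pool']!r}"
                ) from None
            if pool < 1:
                raise ValueError(f"{path}: line {lineno}: pool must be >= 1")
            if amplicon_id in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate amplicon id {amplicon_id!r}"
                )
            seen.add(amplicon_id)
            gene = attrs.get("gene_id", attrs.get("gene", "."))
            records.append((amplicon_id, chrom, start, end, gene, pool))
    if not records:
        logger.warning("%s: no amplicon records found (empty design)", path)
        return pd.DataFrame(columns=DESIGN_COLUMNS, index=pd.Index([], name="amplicon_id"))
    df = pd.DataFrame.from_records(
        records, columns=["amplicon_id"] + DESIGN_COLUMNS
    ).set_index("amplicon_id")
    return df


def write_design_bed(design: pd.DataFrame, path: str | Path) -> None:
    """Serialize a design table back to BED, preserving coordinates and pool."""
    with open(path, "w") as fh:
        for amplicon_id, row in design.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{amplicon_id}\t.\t"
                f"GENE_ID={row['gene']};Pool={row['pool']}\n"
            )


def read_coverage_matrix(path: str | Path) -> pd.DataFrame:
    """Read a barcode/amplicon coverage matrix (either header dialect).

    Returns a depths DataFrame (amplicons x samples), integer-typed when all
    depths are whole numbers. Duplicate amplicon rows, duplicate barcode
    columns, negative depths and non-numeric cells are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: coverage matrix needs an id column and >=1 sample")
    lowered = [h.strip().lower() for h in header]
    if lowered[0] == "gene" and len(lowered) > 1 and lowered[1] == "target":
        id_col, first_sample = header[1], 2
    else:
        id_col, first_sample = header[0], 1
    sample_ids = header[first_sample:]
    dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate barcode column(s): {list(dupes)}")

    raw = pd.read_csv(path, sep="\t", dtype=str, header=0)
    raw.columns = header  # guard against pandas mangling duplicate names
    ids = raw[id_col]
    if ids.duplicated().any():
        bad = ids[ids.duplicated()].unique()
        raise ValueError(f"{path}: duplicate amplicon row(s): {list(bad)}")
    depths = pd.DataFrame(index=pd.Index(ids, name="amplicon_id"))
    for col in sample_ids:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric depth {raw[col].iloc[i]!r} "
                f"(amplicon {ids.iloc[i]!r}, sample {col!r})"
            )
        if (vals < 0).any():
            i = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise ValueError(
                f"{path}: negative depth (amplicon {ids.iloc[i]!r}, sample {col!r})"
            )
        depths[col] = vals.to_numpy()
    arr = depths.to_numpy()
    if np.all(np.mod(arr, 1) == 0):
        depths = depths.astype(np.int64)
    return depths


def write_coverage_matrix(
    depths: pd.DataFrame,
    path: str | Path,
    design: pd.DataFrame | None = None,
    dialect: str = "plain",
) -> None:
    """Write a coverage matrix in either accepted dialect.

    ``dialect='gene_target'`` emits the vendor-style ``Gene\\tTarget`` header
    (gene labels looked up in ``design`` when given).
    """
    out = depths.copy()
    float_fmt = None if out.dtypes.map(pd.api.types.is_integer_dtype).all() else "%.6f"
    if dialect == "gene_target":
        genes = (
            design["gene"].reindex(out.index).fillna(".")
            if design is not None
            else pd.Series(".", index=out.index)
        )
        out = out.copy()
        out.insert(0, "Gene", genes.to_numpy())
        out.index.name = "Target"
        out = out.reset_index().set_index("Gene")[["Target"] + list(depths.columns)]
        out.to_csv(path, sep="\t", float_format=float_fmt)
    elif dialect == "plain":
        out.index.name = "amplicon_id"
        out.to_csv(path, sep="\t", float_format=float_fmt)
    else:
        raise ValueError(f"unknown coverage dialect {dialect!r}")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (``sample_id<TAB>sex`` + optional columns)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: sample metadata needs a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    if "sex" not in meta.columns:
        meta["sex"] = "unknown"
    meta["sex"] = meta["sex"].fillna("unknown").str.lower()
    bad = set(meta["sex"]) - SEX_VALUES
    if bad:
        raise ValueError(f"{path}: unknown sex value(s) {sorted(bad)}")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def join_and_validate(
    design: pd.DataFrame,
    depths: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> AmpliconDataset:
    """Join design and coverage on amplicon id into a sorted dataset.

    Amplicons present in both inputs are retained and sorted by
    (chromosome in natural order, start, amplicon_id); one-sided orphans are
    reported via warnings and recorded on the returned dataset. An empty
    overlap is a hard error.
    """
    shared = design.index.intersection(depths.index)
    if len(shared) == 0:
        raise ValueError("design and coverage matrix share no amplicon ids")
    orphans_design = sorted(design.index.difference(depths.index))
    orphans_matrix = sorted(depths.index.difference(design.index))
    if orphans_design:
        logger.warning(
            "%d design amplicon(s) absent from coverage matrix: %s",
            len(orphans_design), orphans_design,
        )
    if orphans_matrix:
        logger.warning(
            "%d coverage row(s) absent from design: %s",
            len(orphans_matrix), orphans_matrix,
        )
    sub = design.loc[shared]
    order = sorted(
        shared,
        key=lambda a: (chrom_sort_key(sub.at[a, "chrom"]), sub.at[a, "start"], a),
    )
    return AmpliconDataset(
        design=design.loc[order],
        depths=depths.loc[order],
        meta=meta,
        orphans_design=orphans_design,
        orphans_matrix=orphans_matrix,
    )


def write_normalized_matrix(
    norm: pd.DataFrame, retained: pd.Series, path: str | Path
) -> None:
    """Write the normalized-depth matrix (6 decimals, NA for undefined).

    A ``retained`` 0/1 column records the outlier mask so the file round-trips
    through :func:`read_normalized_matrix`.
    """
    out = norm.copy()
    out.insert(0, "retained", retained.reindex(out.index).astype(int))
    out.index.name = "amplicon_id"
    out.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def read_normalized_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="amplicon_id", na_values="NA")
    retained = df.pop("retained").astype(bool)
    return df, retained


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write the calls table in the documented column order (6-decimal floats).

    An empty call list produces a header-only file.
    """
    out = calls.copy() if len(calls) else pd.DataFrame(columns=CALL_COLUMNS)
    missing = [c for c in CALL_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"calls table missing column(s): {missing}")
    out = out[CALL_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
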