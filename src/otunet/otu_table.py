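"""OTU tables: reading, validation, prevalence filtering, log-relative
abundance, and alpha diversity.

An OTU (operational taxonomic unit) table holds integer read counts with
OTUs as rows and samples as columns, plus a taxonomy lineage per OTU and a
group/timepoint label per sample.  Everything downstream of this module —
correlation networks, topology, stability — consumes the
:class:`AbundanceMatrix` produced here.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical rank order used for lineage parsing.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

# Greengenes-style (k__) and Silva-style (D_0__) rank prefixes.
_GG_PREFIXES = {"k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}

UNCLASSIFIED = "Unclassified"


class OtuTableError(ValueError):
    """Malformed OTU table or metadata."""


@dataclass
class OtuTable:
    """Counts matrix (OTU x sample) with taxonomy and sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = OTU ids, columns = sample ids.
    taxonomy : pandas.DataFrame
        One row per OTU (same index as ``counts``), columns = ``RANKS``;
        missing ranks hold ``"Unclassified"``.
    metadata : pandas.DataFrame
        One row per sample (index = sample ids), with at least a ``group``
        column; a ``timepoint`` column is optional.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise OtuTableError("duplicate OTU ids")
        if self.counts.columns.duplicated().any():
            raise OtuTableError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise OtuTableError("negative counts")
        if not self.counts.index.equals(self.taxonomy.index):
            raise OtuTableError("taxonomy index does not match counts index")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise OtuTableError(
                f"samples without metadata rows: {sorted(missing)}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> list[str]:
        """Distinct group labels in metadata order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(str(self.metadata.loc[s, "group"]), None)
        return list(seen)

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(
            counts=self.counts[sample_ids].copy(),
            taxonomy=self.taxonomy.copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def subset_group(self, group: str) -> "OtuTable":
        ids = [
            s
            for s in self.sample_ids
            if str(self.metadata.loc[s, "group"]) == str(group)
        ]
        if not ids:
            raise OtuTableError(f"no samples in group {group!r}")
        return self.subset_samples(ids)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["taxonomy"] = [
            "; ".join(
                f"{p}__{self.taxonomy.loc[o, r]}"
                for p, r in zip("kpcofgs", RANKS)
                if self.taxonomy.loc[o, r] != UNCLASSIFIED
            )
            or UNCLASSIFIED
            for o in self.otu_ids
        ]
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")


@dataclass
class AbundanceMatrix:
    """Log10 relative abundances for the OTUs retained after filtering.

    ``values`` has OTUs as rows and samples as columns; every entry is
    finite.  ``zero_replacement`` records the pseudo-abundance substituted
    for zero counts before the log.
    """

    values: pd.DataFrame
    zero_replacement: float
    retained_otu_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("non-finite log abundances")
        if not self.retained_otu_ids:
            self.retained_otu_ids = list(self.values.index)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Greengenes- or Silva-style lineage string into ranks.

    ``"k__Bacteria; p__Firmicutes"`` and ``"D_0__Bacteria;D_1__Firmicutes"``
    both map kingdom -> Bacteria, phylum -> Firmicutes.  Unparseable or
    missing ranks come back as ``"Unclassified"``.
    """
    out = {r: UNCLASSIFIED for r in RANKS}
    if not isinstance(lineage, str) or not lineage.strip():
        return out
    parsed_any = False
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        if "__" not in token:
            continue
        prefix, _, name = token.partition("__")
        prefix = prefix.strip()
        name = name.strip()
        idx: int | None = None
        if prefix.lower() in _GG_PREFIXES:
            idx = _GG_PREFIXES[prefix.lower()]
        elif prefix.upper().startswith("D_"):
            try:
                idx = int(prefix[2:])
            except ValueError:
                idx = None
        if idx is not None and 0 <= idx < len(RANKS):
            parsed_any = True
            if name:
                out[RANKS[idx]] = name
    if not parsed_any:
        logger.warning("unparseable lineage %r; all ranks Unclassified", lineage)
    return out


def _locate_header(lines: list[str]) -> tuple[int, str]:
    """Return (index of first data line, header line) for an OTU TSV.

    Comment lines starting '#' before the header are skipped; a
    ``#OTU ID`` style header (itself starting with '#') is tolerated.
    """
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            header_idx = i  # last comment line wins as candidate header
            continue
        if header_idx is not None:
            return i, lines[header_idx].lstrip("#")
        # no comment lines at all: first non-empty line is the header
        return i + 1, line
    raise OtuTableError("empty OTU table file")


def read_otu_table(path, metadata_path) -> OtuTable:
    """Read an OTU counts TSV plus a sample-metadata TSV.

    The counts file has the OTU id in the first column, integer counts in
    the middle columns, and a taxonomy lineage in the last column.  The
    metadata file maps ``sample_id`` to ``group`` (and optionally
    ``timepoint``).  Samples lacking a metadata row are rejected.
    """
    with open(path) as fh:
        lines = fh.readlines()
    data_start, header = _locate_header(lines)
    text = header.rstrip("\n") + "\n" + "".join(lines[data_start:])
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise OtuTableError("need OTU id, at least one sample, and taxonomy")

    otu_col, tax_col = df.columns[0], df.columns[-1]
    otu_ids = df[otu_col].astype(str)
    if otu_ids.duplicated().any():
        raise OtuTableError("duplicate OTU ids")
    sample_cols = list(df.columns[1:-1])
    if len(set(sample_cols)) != len(sample_cols):
        raise OtuTableError("duplicate sample columns")

    counts = df[sample_cols].copy()
    try:
        counts = counts.astype(float)
    except (TypeError, ValueError) as exc:
        raise OtuTableError(f"non-numeric counts: {exc}") from None
    if (counts.values < 0).any():
        raise OtuTableError("negative counts")
    if not np.allclose(counts.values, np.round(counts.values)):
        raise OtuTableError("non-integer counts")
    counts = counts.round().astype(np.int64)
    counts.index = pd.Index(otu_ids, name="otu_id")

    taxonomy = pd.DataFrame(
        [parse_lineage(s) for s in df[tax_col]],
        index=counts.index,
        columns=list(RANKS),
    )

    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in metadata.columns or "group" not in metadata.columns:
        raise OtuTableError("metadata needs 'sample_id' and 'group' columns")
    if metadata["sample_id"].duplicated().any():
        raise OtuTableError("duplicate sample ids in metadata")
    metadata = metadata.set_index("sample_id")

    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.5) -> OtuTable:
    """Keep OTUs present (count > 0) in at least ``min_prevalence`` of samples.

    The default 0.5 removes OTUs found in *less than* half the samples, so
    prevalence exactly 0.5 is kept.  Prevalence is computed within the
    samples of ``table`` — filter after subsetting to a group so rarity is
    judged per analysis unit.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prev = (table.counts.values > 0).mean(axis=1)
    keep = prev >= min_prevalence
    if not keep.any():
        raise OtuTableError(
            f"no OTUs survive prevalence filter at {min_prevalence:g}"
        )
    idx = table.counts.index[keep]
    return OtuTable(
        counts=table.counts.loc[idx].copy(),
        taxonomy=table.taxonomy.loc[idx].copy(),
        metadata=table.metadata.copy(),
    )


def log_relative_abundance(
    table: OtuTable,
    zero_factor: float = 0.01,
    full_table: OtuTable | None = None,
) -> AbundanceMatrix:
    """Log10 relative abundances with deterministic zero replacement.

    Relative abundance is count over the *full* per-sample total: pass the
    unfiltered table as ``full_table`` when ``table`` has already been
    row-filtered, so the denominator keeps its compositional meaning.
    Zero counts are replaced by ``zero_factor`` times the smallest nonzero
    relative abundance in the matrix before taking log10.
    """
    totals_src = full_table if full_table is not None else table
    totals = totals_src.counts.values.sum(axis=0).astype(float)
    zero_samples = [
        s for s, t in zip(totals_src.sample_ids, totals) if t == 0
    ]
    if zero_samples:
        raise OtuTableError(f"samples with zero total counts: {zero_samples}")
    col_totals = pd.Series(totals, index=totals_src.sample_ids)[
        table.sample_ids
    ].values

    rel = table.counts.values / col_totals[np.newaxis, :]
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise OtuTableError("abundance matrix is all zero")
    pseudo = zero_factor * nonzero.min()
    rel = np.where(rel > 0, rel, pseudo)
    values = pd.DataFrame(
        np.log10(rel), index=table.counts.index, columns=table.counts.columns
    )
    return AbundanceMatrix(values=values, zero_replacement=float(pseudo))


def _normalize(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return p / total


def shannon(p, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over nonzero p_i.

    Base 2 gives H in bits (the QIIME 1.x convention); pass
    ``base=np.e`` for nats.
    """
    q = _normalize(p)
    q = q[q > 0]
    return float(-(q * (np.log(q) / np.log(base))).sum())


def simpson(p) -> float:
    """Gini-Simpson diversity D = 1 - sum p_i^2 (probability two random
    reads belong to different taxa)."""
    q = _normalize(p)
    return float(1.0 - (q**2).sum())


def alpha_diversity(table: OtuTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices with group labels."""
    rows = []
    for s in table.sample_ids:
        p = table.counts[s].values
        rows.append(
            {
                "sample_id": s,
                "shannon": shannon(p, base=base),
                "simpson": simpson(p),
                "group": str(table.metadata.loc[s, "group"]),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_alpha(groups: list) -> dict:
    """One-way ANOVA across groups of per-sample diversity values.

    For two groups F equals the square of the pooled-variance t statistic.
    Returns ``{"F": ..., "p": ..., "n_groups": ..., "n_total": ...}``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least two samples")
    with warnings.catch_warnings():
        # identical groups give 0/0; we map that to F=0, p=1 below
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero between- and within-group variance
        f, p = 0.0, 1.0
    return {
        "F": float(f),
        "p": float(p),
        "n_groups": len(arrays),
        "n_total": int(sum(g.size for g in arrays)),
    }
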