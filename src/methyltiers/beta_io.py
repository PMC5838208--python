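"""Input handling for methylation beta matrices, site annotations and interval features.

The pipeline consumes three kinds of input:

* a beta-value matrix (CpG sites x samples, values in [0, 1]) together with a
  two-group sample map (reference group, e.g. healthy HSC, versus case group,
  e.g. AML);
* an Illumina-450K-manifest-like site annotation table giving each site's
  chromosome, 1-based position, RefGene names/groups and CpG-island relation;
* optional BED interval files for arbitrary genomic features (lincRNAs,
  enhancers, transposable elements).

Manifest positions are 1-based; all internal interval arithmetic is 0-based
half-open (BED convention). The conversion happens exactly once, in
:func:`map_sites_to_features`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REF = "REF"
CASE = "CASE"

TSS = "TSS"
BODY = "BODY"
INTERGENIC = "INTERGENIC"

#: RefGene groups collapsed into the TSS (promoter-side) region class.
TSS_GROUPS = frozenset({"TSS1500", "TSS200", "5'UTR", "5′UTR"})
#: RefGene groups collapsed into the gene-Body region class.
BODY_GROUPS = frozenset({"1stExon", "Body", "3'UTR", "3′UTR"})

_KNOWN_GROUPS = TSS_GROUPS | BODY_GROUPS


class ValidationError(ValueError):
    """Raised when an input file violates a structural constraint."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix so manifest and BED naming match."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class BetaMatrix:
    """Sites x samples matrix of methylation beta values with two-group labels.

    ``values[i, j]`` is the beta value of site ``site_ids[i]`` in sample
    ``sample_ids[j]``; NaN encodes a missing measurement. ``groups`` maps every
    sample to ``REF`` or ``CASE``.
    """

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValidationError("duplicate site ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        labels = {self.groups[s] for s in self.sample_ids}
        if labels != {REF, CASE}:
            raise ValidationError(
                f"expected exactly the two groups {{{REF}, {CASE}}}, got {sorted(labels)}"
            )
        bad = np.nonzero((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]} outside [0, 1] at site "
                f"{self.site_ids[i]}, sample {self.sample_ids[j]}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = [j for j, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not idx:
            raise ValidationError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def group_values(self, group: str) -> np.ndarray:
        """Sites x n_group view of the beta values of one group."""
        return self.values[:, self.group_columns(group)]


@dataclass
class SiteAnnotation:
    """Genomic context of one CpG site.

    ``gene_names`` and ``gene_groups`` are aligned: entry *k* says that the
    site falls in region ``gene_groups[k]`` of gene ``gene_names[k]`` (a site
    may overlap several genes). ``region_classes`` is derived from the groups
    by :func:`assign_region_class`.
    """

    site_id: str
    chrom: str
    pos: int  # 1-based manifest coordinate
    gene_names: list[str] = field(default_factory=list)
    gene_groups: list[str] = field(default_factory=list)
    cpg_island_relation: str = ""
    region_classes: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if len(self.gene_names) != len(self.gene_groups):
            raise ValidationError(
                f"site {self.site_id}: {len(self.gene_names)} gene names vs "
                f"{len(self.gene_groups)} gene groups"
            )
        if not self.region_classes:
            self.region_classes = assign_region_class(self.gene_groups)


@dataclass
class FeatureIntervals:
    """Genomic intervals of one feature kind, 0-based half-open."""

    kind: str
    records: list[tuple[str, str, int, int]]  # (feature_id, chrom, start, end)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fid, chrom, start, end in self.records:
            if start >= end:
                raise ValidationError(f"feature {fid}: start {start} >= end {end}")
            if fid in seen:
                raise ValidationError(f"duplicate feature id {fid!r} within kind {self.kind!r}")
            seen.add(fid)


def assign_region_class(gene_groups: Iterable[str]) -> frozenset[str]:
    """Map a site's RefGene groups to region classes {TSS, BODY, INTERGENIC}.

    TSS1500/TSS200/5'UTR make the site a TSS-class site, 1stExon/Body/3'UTR a
    Body-class site (both can hold at once because genes overlap); a site with
    no gene annotation is Intergenic.
    """
    groups = list(gene_groups)
    classes: set[str] = set()
    for g in groups:
        if g in TSS_GROUPS:
            classes.add(TSS)
        elif g in BODY_GROUPS:
            classes.add(BODY)
        elif g:
            raise ValidationError(f"unknown RefGene group label {g!r}")
    if not classes:
        return frozenset({INTERGENIC})
    return frozenset(classes)


def read_beta_matrix(matrix_path: str | Path, groups_path: str | Path) -> BetaMatrix:
    """Read a TSV beta matrix (header: sample ids, first column: site ids)
    plus a two-column TSV sample->group map, and validate both."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_nonempty = df.notna() & (df.apply(lambda c: c.str.strip()) != "")
    unparseable = raw_nonempty.to_numpy() & np.isnan(values)
    if unparseable.any():
        i, j = np.argwhere(unparseable)[0]
        raise ValidationError(
            f"non-numeric beta value {df.iat[i, j]!r} at site {df.index[i]}, "
            f"sample {df.columns[j]}"
        )
    gmap = read_group_map(groups_path)
    return BetaMatrix(
        site_ids=[str(s) for s in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        groups=gmap,
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    gmap = dict(zip(df["sample_id"], df["group"]))
    if len(gmap) != len(df):
        raise ValidationError("duplicate sample ids in group map")
    return gmap


def write_beta_matrix(beta: BetaMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    df = pd.DataFrame(beta.values, index=beta.site_ids, columns=beta.sample_ids)
    df.index.name = "site_id"
    df.to_csv(matrix_path, sep="\t", na_rep="")
    with open(groups_path, "w") as fh:
        for s in beta.sample_ids:
            fh.write(f"{s}\t{beta.groups[s]}\n")


def _split_multi(value: object) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    parts = [p.strip() for p in str(value).split(";")]
    return [p for p in parts if p]


def read_annotation(path: str | Path, sep: str | None = None) -> list[SiteAnnotation]:
    """Read a manifest-like annotation table.

    Expected columns: site_id, chrom, pos (1-based), gene_names, gene_groups
    (both semicolon-delimited, possibly empty), island_relation.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"site_id", "chrom", "pos", "gene_names", "gene_groups"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        names = _split_multi(row.gene_names)
        groups = _split_multi(row.gene_groups)
        out.append(
            SiteAnnotation(
                site_id=str(row.site_id),
                chrom=normalize_chrom(row.chrom),
                pos=int(row.pos),
                gene_names=names,
                gene_groups=groups,
                cpg_island_relation=str(getattr(row, "island_relation", "") or ""),
            )
        )
    return out


def write_annotation(annotations: Sequence[SiteAnnotation], path: str | Path) -> None:
    rows = [
        {
            "site_id": a.site_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "gene_names": ";".join(a.gene_names),
            "gene_groups": ";".join(a.gene_groups),
            "island_relation": a.cpg_island_relation,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_intervals(path: str | Path, kind: str) -> FeatureIntervals:
    """Read a BED3+ file (0-based half-open); column 4 is the feature id when present."""
    records: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            fid = fields[3] if len(fields) > 3 and fields[3] else f"{kind}_{lineno}"
            records.append((fid, chrom, start, end))
    return FeatureIntervals(kind=kind, records=records)


def write_intervals(feats: FeatureIntervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fid, chrom, start, end in feats.records:
            fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")


def map_sites_to_features(
    sites: Sequence[SiteAnnotation], feats: FeatureIntervals
) -> dict[str, list[str]]:
    """Assign CpG sites to the intervals that contain them.

    A site at 1-based position ``p`` lies in the half-open interval
    ``[start, end)`` iff ``start <= p - 1 < end``. Features containing no site
    are absent from the returned map. Strand is ignored.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for s in sites:
        by_chrom.setdefault(normalize_chrom(s.chrom), []).append((s.pos - 1, s.site_id))
    for lst in by_chrom.values():
        lst.sort()

    out: dict[str, list[str]] = {}
    for fid, chrom, start, end in feats.records:
        positions = by_chrom.get(normalize_chrom(chrom))
        if not positions:
            continue
        pos0 = [p for p, _ in positions]
        lo = int(np.searchsorted(pos0, start, side="left"))
        hi = int(np.searchsorted(pos0, end, side="left"))
        if hi > lo:
            out[fid] = [positions[k][1] for k in range(lo, hi)]
    return out
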