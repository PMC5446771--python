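"""Core tabular containers and TSV readers/writers.

Genotypes are stored as unordered two-character allele pairs (e.g. ``"AC"``,
missing = ``"NN"``), one row per sample and one column per bi-allelic locus.
Sample metadata carries the stratification columns the analyses rely on
(population, environment type, sex, full-sib family, cohort year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_CALL = "NN"
ENVIRONMENTS = ("fragmented", "continuous")
SEXES = ("male", "female")

META_COLUMNS = ["population", "environment", "sex", "family", "year"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class LocusAlleles:
    """Major/minor allele designation for one locus (global, frequency-folded)."""

    major: str
    minor: str | None  # None when the locus is monomorphic


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of unordered allele-pair calls."""

    df: pd.DataFrame
    _alleles: dict[str, LocusAlleles] = field(default_factory=dict, repr=False)

    # -- construction -----------------------------------------------------
    def __post_init__(self) -> None:
        self.df = self.df.rename_axis("sample_id")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise DataError(f"duplicated sample id {dup!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
        return cls(df.fillna(MISSING_CALL))

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    # -- basic views ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def loci(self) -> list[str]:
        return list(self.df.columns)

    def calls(self, locus: str) -> pd.Series:
        return self.df[locus]

    # -- allele bookkeeping ----------------------------------------------
    def alleles(self, locus: str) -> LocusAlleles:
        """Global major/minor designation at *locus* (minor = rarer allele).

        Ties are broken alphabetically (the alphabetically later allele is
        called minor) so the designation is deterministic.
        """
        if locus not in self._alleles:
            counts: dict[str, int] = {}
            for call in self.df[locus]:
                if call == MISSING_CALL:
                    continue
                if len(call) != 2:
                    raise DataError(f"malformed call {call!r} at locus {locus}")
                for a in call:
                    counts[a] = counts.get(a, 0) + 1
            if len(counts) > 2:
                raise DataError(
                    f"locus {locus} has {len(counts)} distinct alleles; "
                    "bi-allelic data required"
                )
            if not counts:
                self._alleles[locus] = LocusAlleles(major="?", minor=None)
            elif len(counts) == 1:
                (only,) = counts
                self._alleles[locus] = LocusAlleles(major=only, minor=None)
            else:
                (a1, c1), (a2, c2) = sorted(counts.items())
                if c1 == c2:
                    major, minor = a1, a2
                elif c1 > c2:
                    major, minor = a1, a2
                else:
                    major, minor = a2, a1
                self._alleles[locus] = LocusAlleles(major=major, minor=minor)
        return self._alleles[locus]

    def minor_counts(self) -> pd.DataFrame:
        """Numeric minor-allele counts (0/1/2, NaN for missing calls)."""
        cols = {}
        for locus in self.loci:
            al = self.alleles(locus)
            col = np.full(len(self.df), np.nan)
            for i, call in enumerate(self.df[locus]):
                if call == MISSING_CALL:
                    continue
                col[i] = 0.0 if al.minor is None else float(call.count(al.minor))
            cols[locus] = col
        return pd.DataFrame(cols, index=self.df.index)

    def mask(self, locus: str, sample_ids) -> "GenotypeMatrix":
        """Return a copy with the given samples' calls at *locus* set missing."""
        df = self.df.copy()
        df.loc[list(sample_ids), locus] = MISSING_CALL
        return GenotypeMatrix(df)

    def drop_loci(self, loci) -> "GenotypeMatrix":
        return GenotypeMatrix(self.df.drop(columns=list(loci)))


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table."""
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    meta.index = meta.index.astype(str)
    return validate_samples(meta)


def validate_samples(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"sample table lacks columns {missing}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise DataError(f"duplicated sample id {dup!r}")
    bad_env = set(meta["environment"]) - set(ENVIRONMENTS)
    if bad_env:
        raise DataError(f"unknown environment labels {sorted(bad_env)}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise DataError(f"unknown sex labels {sorted(bad_sex)}")
    return meta


def write_samples(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    traits = pd.read_csv(path, sep="\t", index_col="sample_id")
    traits.index = traits.index.astype(str)
    if traits.index.has_duplicates:
        dup = traits.index[traits.index.duplicated()][0]
        raise DataError(f"duplicated sample id {dup!r}")
    return traits


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    out = traits.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_alignment(geno: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Every genotyped sample must be described in the metadata."""
    orphan = set(geno.samples) - set(meta.index)
    if orphan:
        raise DataError(
            f"samples present in genotypes but not metadata: {sorted(orphan)[:5]}"
        )


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF import: bi-allelic records, GT field only.

    Intended for interoperability; the native interchange format is TSV.
    """
    samples: list[str] = []
    loci: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                raise DataError(f"non-bi-allelic VCF record at {chrom}:{pos}")
            name = vid if vid not in (".", "") else f"{chrom}_{pos}"
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            calls = []
            for entry in parts[9:]:
                gt = entry.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    calls.append(MISSING_CALL)
                else:
                    a, b = (ref if x == "0" else alt for x in gt.split("/"))
                    calls.append("".join(sorted(a + b)))
            loci.append(name)
            rows.append(calls)
    df = pd.DataFrame(
        np.array(rows).T if rows else [], index=samples, columns=loci, dtype=str
    )
    return GenotypeMatrix(df)
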