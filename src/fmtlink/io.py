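"""Domain types and readers/writers for FMT triad metadata, per-SGB distance
sets and the tabular inputs of the pipeline.

All tables are TSV with a header row, UTF-8, "." decimal; missing values are
written as empty strings and read as NaN (empty string or "NA" accepted).
Trees are newick with leaf names equal to sample ids. Sample roles are always
explicit in the metadata table, never inferred from sample-id naming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

Role = Literal["donor", "pre", "post"]

ROLES: tuple[str, ...] = ("donor", "pre", "post")

#: Number of significant digits used when serializing floating-point tables.
#: Round-trips are lossless at this precision.
FLOAT_FORMAT = "%.12g"

_NA_VALUES = ["", "NA"]


@dataclass(frozen=True)
class SampleRecord:
    """One row of the sample-metadata table.

    ``donor_id`` is the *subject id* of the donor serving this recipient;
    it is empty on donor rows (a donor's own sample does not reference a
    donor). Donor rows that no recipient references are allowed and act as
    extra unrelated-only samples (e.g. baseline samples of an external
    cohort added to enrich the unrelated-pair pool).
    """

    sample_id: str
    subject_id: str
    role: Role
    substudy: str
    donor_id: str = ""


@dataclass(frozen=True)
class Triad:
    """One FMT event: donor sample, recipient pre-FMT and post-FMT samples."""

    subject_id: str
    substudy: str
    donor_id: str
    donor_sample: str
    pre_sample: str
    post_sample: str

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.donor_sample, self.pre_sample, self.post_sample)


class TriadTable:
    """Validated collection of :class:`SampleRecord` rows.

    A triad is the sample trio (donor, recipient pre-FMT, recipient
    post-FMT) defining one transplantation event. A donor may serve
    several recipients and therefore appear in multiple triads.
    """

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: list[SampleRecord] = list(records)
        self._validate()

    def _validate(self) -> None:
        if not self.records:
            raise IntegrityError("triad table is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.role not in ROLES:
                raise FormatError(
                    f"sample {rec.sample_id!r}: unknown role {rec.role!r}"
                )
            if rec.sample_id in seen:
                raise FormatError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)

        donors = {r.subject_id: r for r in self.records if r.role == "donor"}
        by_subject: dict[str, dict[str, SampleRecord]] = {}
        for rec in self.records:
            if rec.role in ("pre", "post"):
                if not rec.donor_id:
                    raise IntegrityError(
                        f"recipient sample {rec.sample_id!r} has no donor_id"
                    )
                if rec.donor_id not in donors:
                    raise IntegrityError(
                        f"recipient sample {rec.sample_id!r} references donor "
                        f"{rec.donor_id!r} with no donor sample in the table"
                    )
                by_subject.setdefault(rec.subject_id, {})
                if rec.role in by_subject[rec.subject_id]:
                    raise IntegrityError(
                        f"subject {rec.subject_id!r} has more than one "
                        f"{rec.role!r} sample"
                    )
                by_subject[rec.subject_id][rec.role] = rec
        for subject, roles in by_subject.items():
            pre, post = roles.get("pre"), roles.get("post")
            if pre is not None and post is not None:
                if pre.donor_id != post.donor_id:
                    raise IntegrityError(
                        f"subject {subject!r}: pre and post rows name "
                        "different donors"
                    )
                if pre.substudy != post.substudy:
                    raise IntegrityError(
                        f"subject {subject!r}: pre and post rows name "
                        "different sub-studies"
                    )
        self._donors = donors
        self._by_subject = by_subject

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subject_of(self, sample_id: str) -> str:
        return self.record(sample_id).subject_id

    @property
    def substudies(self) -> list[str]:
        return sorted({r.substudy for r in self.records})

    def triads(self) -> list[Triad]:
        """Complete triads only: subjects with both a pre and a post sample."""
        out = []
        for subject in sorted(self._by_subject):
            roles = self._by_subject[subject]
            if "pre" in roles and "post" in roles:
                post = roles["post"]
                donor = self._donors[post.donor_id]
                out.append(
                    Triad(
                        subject_id=subject,
                        substudy=post.substudy,
                        donor_id=post.donor_id,
                        donor_sample=donor.sample_id,
                        pre_sample=roles["pre"].sample_id,
                        post_sample=post.sample_id,
                    )
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.subject_id, r.role, r.substudy, r.donor_id)
                for r in self.records
            ],
            columns=["sample_id", "subject_id", "role", "substudy", "donor_id"],
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DistanceSet:
    """Pairwise normalized phylogenetic distances for one SGB.

    ``D`` is a symmetric matrix with zero diagonal over ``sample_ids`` —
    the samples in which this SGB was strain-profiled. ``marker_counts``
    gives the number of StrainPhlAn-style marker genes recovered per
    sample (used by the ≥20-marker filter). ``normalizer`` records the
    total branch length used to normalize patristic distances, or ``None``
    when the matrix was supplied pre-normalized.
    """

    sgb_id: str
    sample_ids: list[str]
    D: np.ndarray
    marker_counts: dict[str, int] = field(default_factory=dict)
    normalizer: float | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise FormatError(f"SGB {self.sgb_id}: duplicate sample ids")
        if self.D.shape != (n, n):
            raise FormatError(
                f"SGB {self.sgb_id}: matrix shape {self.D.shape} does not "
                f"match {n} samples"
            )
        if not np.all(np.isfinite(self.D)):
            raise FormatError(f"SGB {self.sgb_id}: non-finite distances")
        if np.any(self.D < 0):
            raise FormatError(f"SGB {self.sgb_id}: negative distances")
        if np.max(np.abs(self.D - self.D.T), initial=0.0) > 1e-9:
            raise FormatError(f"SGB {self.sgb_id}: matrix is not symmetric")
        if np.max(np.abs(np.diag(self.D)), initial=0.0) > 1e-12:
            raise FormatError(f"SGB {self.sgb_id}: non-zero diagonal")
        self.D = (self.D + self.D.T) / 2.0
        np.fill_diagonal(self.D, 0.0)
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def distance(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    def subset(self, keep: Iterable[str]) -> "DistanceSet":
        keep = [s for s in self.sample_ids if s in set(keep)]
        idx = [self._index[s] for s in keep]
        return DistanceSet(
            sgb_id=self.sgb_id,
            sample_ids=keep,
            D=self.D[np.ix_(idx, idx)],
            marker_counts={s: self.marker_counts[s] for s in keep if s in self.marker_counts},
            normalizer=self.normalizer,
        )


# ---------------------------------------------------------------------------
# Triad table I/O
# ---------------------------------------------------------------------------

_TRIAD_COLUMNS = ["sample_id", "subject_id", "role", "substudy", "donor_id"]


def read_triad_table(path: str | Path) -> TriadTable:
    """Read the sample-metadata TSV mapping samples to FMT triads."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = [c for c in _TRIAD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            role=row.role,
            substudy=row.substudy,
            donor_id=row.donor_id,
        )
        for row in df.itertuples()
    ]
    return TriadTable(records)


def write_triad_table(table: TriadTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distance I/O
# ---------------------------------------------------------------------------


def read_distances(
    path: str | Path,
    mode: Literal["matrix", "newick"] = "matrix",
    sgb_id: str | None = None,
    marker_counts: dict[str, int] | None = None,
) -> DistanceSet:
    """Read a per-SGB distance set from a square TSV or a newick tree.

    In ``newick`` mode the patristic distance (sum of branch lengths on
    the path) between each leaf pair is computed and divided by the
    tree's total branch length, so values are comparable across SGBs
    whose trees differ in depth. In ``matrix`` mode the TSV is taken as
    already normalized and only checked for symmetry.
    """
    path = Path(path)
    if sgb_id is None:
        sgb_id = path.stem
    if mode == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise FormatError(f"{path}: row and column headers differ")
        return DistanceSet(
            sgb_id=sgb_id,
            sample_ids=[str(s) for s in df.index],
            D=df.to_numpy(dtype=float),
            marker_counts=marker_counts or {},
            normalizer=None,
        )
    if mode != "newick":
        raise ValueError(f"unknown mode {mode!r}")

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"{path}: duplicate leaf names ({exc})") from exc
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise FormatError(f"{path}: duplicate leaf names")
    total = tree.length()
    if total <= 0:
        raise FormatError(f"{path}: tree has no positive branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j]) / total
            D[i, j] = D[j, i] = d
    return DistanceSet(
        sgb_id=sgb_id,
        sample_ids=[t.label for t in taxa],
        D=D,
        marker_counts=marker_counts or {},
        normalizer=total,
    )


def write_distances(dset: DistanceSet, path: str | Path) -> None:
    df = pd.DataFrame(dset.D, index=dset.sample_ids, columns=dset.sample_ids)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_marker_counts(path: str | Path) -> pd.DataFrame:
    """Long TSV (sgb_id, sample_id, n_markers) of marker counts per profile."""
    df = pd.read_csv(path, sep="\t", dtype={"sgb_id": str, "sample_id": str})
    for col in ("sgb_id", "sample_id", "n_markers"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def write_marker_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular inputs (validated DataFrames)
# ---------------------------------------------------------------------------


def validate_abundance(df: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Relative-abundance table, samples in rows, SGBs in columns."""
    values = df.to_numpy(dtype=float)
    if np.any(values < -tol) or np.any(values > 1 + tol):
        raise IntegrityError("abundance values outside [0, 1]")
    sums = np.nansum(values, axis=1)
    if np.any(sums > 1 + tol):
        raise IntegrityError("per-sample abundance sums exceed 1")
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)
    return validate_abundance(df)


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


_CLINICAL_COLUMNS = ["subject_id", "parameter", "time", "value", "units"]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing column(s) {missing}")
    bad_time = set(df["time"]) - {"pre", "post"}
    if bad_time:
        raise FormatError(f"clinical table has unknown time value(s) {bad_time}")
    keys = df[["subject_id", "parameter", "time"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise IntegrityError(
            f"duplicate clinical measurement for {tuple(dup)}"
        )
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Long clinical table: subject_id, parameter, time ∈ {pre, post}, value, units."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "parameter": str, "time": str, "units": str},
        na_values=_NA_VALUES,
        keep_default_na=True,
    )
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(df).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_metabolites(path: str | Path) -> pd.DataFrame:
    """Metabolite intensity table indexed by (subject_id, time)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES)
    for col in ("subject_id", "time"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.set_index(["subject_id", "time"])
    values = df.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise IntegrityError("negative metabolite intensity")
    return df


def write_metabolites(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Read a TOML config file into a plain dict."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


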