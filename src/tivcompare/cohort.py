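"""Cohort container, CSV round-trip, and stratified splitting.

A cohort is a subjects × regions table of grey-matter volumes (ml) together
with each subject's sex label (F/M) and total intracranial volume (TIV, ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("subject_id", "sex", "tiv_ml")

_SEX_ALIASES = {
    "f": "F", "female": "F", "F": "F",
    "m": "M", "male": "M", "M": "M",
}


class CohortError(ValueError):
    """Raised on malformed cohort tables or invalid split requests."""


@dataclass
class CohortTable:
    """Subjects × regions volume matrix with sex labels and TIV.

    Parameters
    ----------
    subject_id : array of unique identifiers.
    sex : array of 'F'/'M' labels (both must be present).
    tiv : per-subject total intracranial volume in ml, strictly positive.
    volumes : (n_subjects, n_regions) array of regional volumes in ml,
        strictly positive.
    region_names : unique, ordered region labels.
    """

    subject_id: np.ndarray
    sex: np.ndarray
    tiv: np.ndarray
    volumes: np.ndarray
    region_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.sex = np.asarray(self.sex, dtype=object)
        self.tiv = np.asarray(self.tiv, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.region_names = list(self.region_names)
        n = len(self.subject_id)
        if len(np.unique(self.subject_id)) != n:
            raise CohortError("subject_id values must be unique")
        if self.volumes.shape != (n, len(self.region_names)):
            raise CohortError(
                f"volumes shape {self.volumes.shape} does not match "
                f"{n} subjects x {len(self.region_names)} regions"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise CohortError("region names must be unique")
        bad_sex = set(self.sex) - {"F", "M"}
        if bad_sex:
            raise CohortError(f"unknown sex labels: {sorted(bad_sex)}")
        if not ({"F", "M"} <= set(self.sex)):
            raise CohortError("both sex labels (F and M) must be present")
        if np.any(~np.isfinite(self.tiv)) or np.any(self.tiv <= 0):
            bad = self.subject_id[~(np.isfinite(self.tiv) & (self.tiv > 0))]
            raise CohortError(f"non-positive or missing TIV for subjects: {list(bad[:5])}")
        if np.any(~np.isfinite(self.volumes)) or np.any(self.volumes <= 0):
            rows = np.where(~np.all(np.isfinite(self.volumes) & (self.volumes > 0), axis=1))[0]
            raise CohortError(
                f"non-positive or missing volumes for subjects: {list(self.subject_id[rows[:5]])}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def mask(self, sex: str) -> np.ndarray:
        return self.sex == sex

    def subset(self, ids) -> "CohortTable":
        """Return the sub-cohort containing exactly the given subjects (in id order given)."""
        index = {s: i for i, s in enumerate(self.subject_id)}
        try:
            rows = np.array([index[s] for s in ids])
        except KeyError as exc:
            raise CohortError(f"unknown subject id: {exc.args[0]}") from exc
        return CohortTable(
            subject_id=self.subject_id[rows],
            sex=self.sex[rows],
            tiv=self.tiv[rows],
            volumes=self.volumes[rows],
            region_names=self.region_names,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame({"subject_id": self.subject_id, "sex": self.sex, "tiv_ml": self.tiv})
        body = pd.DataFrame(self.volumes, columns=self.region_names, index=head.index)
        return pd.concat([head, body], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "CohortTable":
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"missing required columns: {missing}")
        regions = [c for c in df.columns if c not in RESERVED_COLUMNS]
        if not regions:
            raise CohortError("no region columns found")
        sex = df["sex"].astype(str).str.strip().map(lambda s: _SEX_ALIASES.get(s.lower()))
        if sex.isna().any():
            bad = df.loc[sex.isna(), "subject_id"].tolist()
            raise CohortError(f"unknown sex labels for subjects: {bad[:5]}")
        return cls(
            subject_id=df["subject_id"].to_numpy(),
            sex=sex.to_numpy(dtype=object),
            tiv=df["tiv_ml"].to_numpy(dtype=float),
            volumes=df[regions].to_numpy(dtype=float),
            region_names=regions,
            meta=meta or {},
        )


def write_cohort(cohort: CohortTable, path, seed: int | None = None) -> None:
    """Write a cohort as CSV; generator seed (if any) is recorded as a comment line."""
    seed = seed if seed is not None else cohort.meta.get("seed")
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        cohort.to_frame().to_csv(fh, index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV/TSV (auto-detected delimiter, '#' comment lines allowed)."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    return CohortTable.from_frame(df)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, sex-balanced subject-id sets for train / test / external-validation use."""

    train_ids: tuple
    test_ids: tuple
    external_ids: tuple

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.test_ids), set(self.external_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise CohortError("split sets must be disjoint")


def split_cohort(
    cohort: CohortTable,
    fractions: tuple[float, ...] = (0.7,),
    seed: int = 0,
    min_per_sex: int = 1,
) -> SplitSpec:
    """Stratified (sex-balanced) split of a cohort into up to three id sets.

    Per-sex counts in split k are round(fraction_k * n_sex) for each stated
    fraction; the remainder goes to the last split.  With one fraction the
    result is train/test; with two, train/test/external.
    """
    fractions = tuple(fractions)
    if not fractions or sum(fractions) > 1 + 1e-12:
        raise CohortError("fractions must be non-empty and sum to at most 1")
    rng = np.random.default_rng(seed)
    # per-sex balanced counts: use the smaller sex as the common n per split
    per_sex_ids = {}
    for s in ("F", "M"):
        ids = cohort.subject_id[cohort.mask(s)]
        per_sex_ids[s] = rng.permutation(ids)
    n_common = min(len(per_sex_ids["F"]), len(per_sex_ids["M"]))
    counts = [int(np.floor(f * n_common + 0.5)) for f in fractions]
    counts.append(n_common - sum(counts))
    if any(c < min_per_sex for c in counts):
        raise CohortError(
            f"insufficient subjects: per-sex split counts {counts} below minimum {min_per_sex}"
        )
    splits = []
    for s_idx in range(len(counts)):
        lo = sum(counts[:s_idx])
        hi = lo + counts[s_idx]
        ids = np.concatenate([per_sex_ids["F"][lo:hi], per_sex_ids["M"][lo:hi]])
        splits.append(tuple(ids))
    while len(splits) < 3:
        splits.append(tuple())
    return SplitSpec(train_ids=splits[0], test_ids=splits[1], external_ids=splits[2])
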