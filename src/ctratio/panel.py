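"""Marker panel, Ct matrix ingestion, and pairwise dCt ratio variables.

The assay measures threshold-cycle (Ct) values for 25 target miRNAs and 3
reference miRNAs per bone-marrow sample.  Classification works on *ratio
variables*: for markers A and B the variable ``A:B`` is Ct(A) - Ct(B), i.e.
the binary logarithm of the concentration ratio B/A under ideal PCR
efficiency.  A pseudo-marker ``nf3`` — the geometric mean of the three
reference Cts — joins the 28 assayed markers, giving C(29, 2) = 406
unordered pairs on the default panel.

Because every ratio is a within-sample difference of Cts, any per-sample
loading/input offset cancels exactly; this is the property that makes the
variables comparable across samples without absolute quantification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

GROUPS = ("NTP", "ALL", "AML")

#: The 25 target miRNAs, in assay listing order (mature-arm suffixes dropped
#: for display: miR-100 is miR-100-5p, miR-451a and let7a are unsuffixed).
DEFAULT_TARGETS = (
    "miR-100", "miR-124", "miR-126", "miR-128", "miR-146a",
    "miR-150", "miR-155", "miR-18a", "miR-181a", "miR-181b",
    "miR-196b", "miR-20a", "miR-21", "miR-210", "miR-221",
    "miR-223", "miR-24", "miR-26a", "miR-29b", "miR-451a",
    "miR-9", "miR-92a", "miR-96", "miR-99a", "let7a",
)

#: Reference miRNAs entering the nf3 normalization factor
#: (miR-103a-3p, miR-191-5p, miR-378-3p).
DEFAULT_REFERENCES = ("miR-103a", "miR-191", "miR-378")

NF3 = "nf3"

#: Default plausible Ct window (cycles); values outside fail validation.
DEFAULT_CT_RANGE = (5.0, 45.0)


@dataclass(frozen=True)
class MarkerPanel:
    """Identity and roles of the assayed markers.

    Parameters
    ----------
    targets
        Target miRNA names, in canonical (assay) order.
    references
        Reference miRNA names used to build the nf3 pseudo-marker.
    use_nf3
        Whether the nf3 pseudo-marker participates in variable enumeration.
        Requires at least one reference.
    """

    targets: tuple[str, ...] = DEFAULT_TARGETS
    references: tuple[str, ...] = DEFAULT_REFERENCES
    use_nf3: bool = True
    nf3_name: str = NF3

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "references", tuple(self.references))
        markers = self.targets + self.references
        if len(set(markers)) != len(markers):
            raise ConfigError("panel markers must be unique and disjoint "
                              "between targets and references")
        if self.nf3_name in markers:
            raise ConfigError(f"marker name {self.nf3_name!r} collides with "
                              "the nf3 pseudo-marker")
        if self.use_nf3 and not self.references:
            raise ConfigError("nf3 requires at least one reference marker")

    @property
    def markers(self) -> tuple[str, ...]:
        """All assayed markers (targets then references), without nf3."""
        return self.targets + self.references

    @property
    def entities(self) -> tuple[str, ...]:
        """Markers eligible for pairing: assayed markers plus nf3 if enabled."""
        if self.use_nf3:
            return self.markers + (self.nf3_name,)
        return self.markers

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            targets=tuple(spec["targets"]),
            references=tuple(spec.get("references", ())),
            use_nf3=bool(spec.get("use_nf3", True)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"targets": list(self.targets),
                 "references": list(self.references),
                 "use_nf3": self.use_nf3},
                fh, sort_keys=False)


@dataclass(frozen=True, order=True)
class RatioVariable:
    """An unordered marker pair rendered as the signed covariate Ct(A)-Ct(B)."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigError("ratio variable needs two distinct markers")

    @property
    def name(self) -> str:
        return f"{self.numerator}:{self.denominator}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    @classmethod
    def from_name(cls, name: str) -> "RatioVariable":
        num, _, den = name.partition(":")
        if not den:
            raise ConfigError(f"cannot parse ratio variable {name!r}")
        return cls(num, den)


@dataclass
class CtMatrix:
    """Samples x markers table of raw Ct values with group labels.

    ``ct`` is indexed by sample id with one column per assayed marker;
    ``groups`` is a parallel Series of labels from :data:`GROUPS`.
    """

    ct: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.ct.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.ct.index

    @property
    def n_samples(self) -> int:
        return len(self.ct)

    def validate(self, panel: MarkerPanel,
                 ct_range: tuple[float, float] = DEFAULT_CT_RANGE) -> "CtMatrix":
        """Check completeness, finiteness and plausibility; return self."""
        if self.ct.index.duplicated().any():
            dupes = self.ct.index[self.ct.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        missing_cols = [m for m in panel.markers if m not in self.ct.columns]
        if missing_cols:
            raise ValidationError(f"Ct matrix lacks panel markers: {missing_cols}")
        bad_groups = set(self.groups.unique()) - set(GROUPS)
        if bad_groups or self.groups.isna().any():
            raise ValidationError(
                f"group labels must be in {GROUPS}; found {sorted(map(str, bad_groups))}")
        block = self.ct[list(panel.markers)]
        if block.isna().any().any():
            sample, marker = next(
                (i, c) for c in block.columns for i in block.index[block[c].isna()])
            raise ValidationError(
                f"missing Ct for marker {marker!r} in sample {sample!r}")
        values = block.to_numpy(float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite Ct value in matrix")
        lo, hi = ct_range
        if (values < lo).any() or (values > hi).any():
            raise ValidationError(
                f"Ct values outside plausible range [{lo}, {hi}] cycles")
        return self

    def subset(self, mask) -> "CtMatrix":
        return CtMatrix(self.ct.loc[mask], self.groups.loc[mask])

    def to_frame(self) -> pd.DataFrame:
        """Wide export: sample_id index, ``group`` column, marker columns."""
        out = self.ct.copy()
        out.insert(0, "group", self.groups)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CtMatrix":
        if "group" not in df.columns:
            raise ValidationError("Ct table needs a 'group' column")
        groups = df["group"].astype(str)
        ct = df.drop(columns=["group"]).astype(float)
        return cls(ct, groups)

    @classmethod
    def read_csv(cls, path, panel: MarkerPanel | None = None) -> "CtMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        matrix = cls.from_frame(df)
        if panel is not None:
            matrix.validate(panel)
        return matrix


def compute_nf3(ct_row: Mapping[str, float] | pd.Series, panel: MarkerPanel,
                mode: str = "geometric_ct") -> float:
    """Normalization-factor Ct for one sample.

    ``geometric_ct`` (default) takes the geometric mean of the three raw
    reference Ct values.  ``arithmetic_ct`` averages the Cts arithmetically,
    which equals the geometric mean of the reference *concentrations* —
    the construction the geNorm framework actually prescribes.  Both lie
    within [min, max] of the inputs; for typical reference Cts (tight range
    around 25–30 cycles) the two differ by well under 0.1 cycles.
    """
    refs = []
    for marker in panel.references:
        try:
            value = float(ct_row[marker])
        except (KeyError, TypeError):
            raise ValidationError(f"missing reference marker {marker!r} "
                                  "while computing nf3") from None
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"reference marker {marker!r} has "
                                  f"non-positive Ct {value!r}")
        refs.append(value)
    arr = np.asarray(refs, float)
    if mode == "geometric_ct":
        return float(np.exp(np.mean(np.log(arr))))
    if mode == "arithmetic_ct":
        return float(np.mean(arr))
    raise ConfigError(f"unknown nf3_mode {mode!r}")


def nf3_column(matrix: CtMatrix, panel: MarkerPanel,
               mode: str = "geometric_ct") -> pd.Series:
    """Vectorised nf3 per sample (matches compute_nf3 row-wise)."""
    block = matrix.ct[list(panel.references)].to_numpy(float)
    if (block <= 0).any() or not np.isfinite(block).all():
        raise ValidationError("non-positive or non-finite reference Ct")
    if mode == "geometric_ct":
        values = np.exp(np.log(block).mean(axis=1))
    elif mode == "arithmetic_ct":
        values = block.mean(axis=1)
    else:
        raise ConfigError(f"unknown nf3_mode {mode!r}")
    return pd.Series(values, index=matrix.sample_ids, name=panel.nf3_name)


def enumerate_variables(panel: MarkerPanel) -> list[RatioVariable]:
    """All unordered marker pairs in canonical order.

    Entities follow panel order (targets, references, then nf3); within a
    pair the earlier entity is the numerator, which fixes the sign
    convention.  The default panel (28 markers + nf3) yields C(29,2) = 406
    variables.
    """
    entities = panel.entities
    return [RatioVariable(a, b) for a, b in itertools.combinations(entities, 2)]


def evaluate_variables(matrix: CtMatrix,
                       variables: Sequence[RatioVariable],
                       panel: MarkerPanel,
                       nf3_mode: str = "geometric_ct") -> pd.DataFrame:
    """Samples x variables table of Ct(numerator) - Ct(denominator).

    nf3 is computed per sample on the fly.  Adding a constant to every Ct
    of a sample leaves its whole row unchanged (per-sample offsets cancel;
    exact for arithmetic nf3, and exact in floating point for geometric nf3
    only when the offset is zero — see the methods note).
    """
    table = matrix.ct.copy()
    entities = set(panel.entities)
    needed = {v.numerator for v in variables} | {v.denominator for v in variables}
    unknown = needed - entities
    if unknown:
        raise ConfigError(f"variables reference markers absent from the "
                          f"panel: {sorted(unknown)}")
    if panel.nf3_name in needed:
        table[panel.nf3_name] = nf3_column(matrix, panel, mode=nf3_mode)
    data = {v.name: table[v.numerator] - table[v.denominator] for v in variables}
    return pd.DataFrame(data, index=matrix.sample_ids)


def value_table_long(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Long-format export ``sample_id, group, variable, value`` for plotting."""
    long = values.stack().rename("value").reset_index()
    long.columns = ["sample_id", "variable", "value"]
    long.insert(1, "group", groups.reindex(long["sample_id"]).to_numpy())
    return long
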