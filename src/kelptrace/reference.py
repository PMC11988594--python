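"""Reference table of kelp volatile organic compounds (VOCs).

The package ships a machine-readable transcription of the published GC-IMS
integration table: 115 VOC features, each annotated with compound identity,
monomer/dimer form, chemical class, retention index (RI), retention time
(Rt, s), relative drift time (Dt, a.u.), and — per origin city (Rongcheng,
Dalian, Xiapu; n = 30 each) — the signal-intensity mean, standard deviation
and Duncan grouping letter, plus the one-way ANOVA p-value and odor
descriptors.  This table parameterizes the synthetic cohort generator and
anchors all count-based checks.

p-values printed as "<0.001" are stored with a placeholder value of 0.0005
and a ``below_threshold`` bound of 0.001; all comparisons consult the bound,
never the placeholder.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ORIGINS",
    "VocFeature",
    "OriginStats",
    "PValue",
    "ReferenceTable",
    "ReferenceValidationError",
    "load_reference_table",
    "write_reference_table",
    "summarize_classes",
    "count_significant",
]

#: Origin cities in label-code order (Rongcheng=0, Dalian=1, Xiapu=2).
ORIGINS = ("Rongcheng", "Dalian", "Xiapu")

_ORIGIN_COLS = ("rongcheng", "dalian", "xiapu")

CHEM_CLASSES = frozenset(
    {"acid", "pyrazine", "aldehyde", "alcohol", "ether", "furan", "ester",
     "ketone", "other", "unidentified"}
)

_COLUMNS = [
    "feature_id", "compound_name", "form", "chem_class", "RI", "Rt_sec",
    "Dt_au",
    "mean_rongcheng", "sd_rongcheng", "letter_rongcheng",
    "mean_dalian", "sd_dalian", "letter_dalian",
    "mean_xiapu", "sd_xiapu", "letter_xiapu",
    "p_value", "odor_description",
]


class ReferenceValidationError(ValueError):
    """Raised when the reference table violates a structural invariant."""


@dataclass(frozen=True)
class VocFeature:
    """One VOC feature (a monomer or dimer signal of one compound)."""

    feature_id: str
    compound_name: str
    form: str  # "monomer" | "dimer" | "single"
    chem_class: str
    ri: float | None = None
    rt: float | None = None
    dt: float | None = None
    odor_descriptors: tuple[str, ...] = ()

    @property
    def identified(self) -> bool:
        return self.chem_class != "unidentified"


@dataclass(frozen=True)
class OriginStats:
    """Per-origin signal-intensity summary for one feature."""

    feature_id: str
    origin: int  # 0=Rongcheng, 1=Dalian, 2=Xiapu
    mean_intensity: float
    sd_intensity: float
    duncan_letter: str


@dataclass(frozen=True)
class PValue:
    """ANOVA p-value as printed: either a value or an upper bound.

    ``below_threshold`` is the bound for "<x" entries (value then holds a
    placeholder of x/2 and must not be compared directly).
    """

    value: float
    below_threshold: float | None = None

    def is_below(self, alpha: float) -> bool:
        """Strict comparison p < alpha honouring the printed bound."""
        if self.below_threshold is not None:
            return self.below_threshold <= alpha
        return self.value < alpha

    def __str__(self) -> str:  # round-trips the printed form
        if self.below_threshold is not None:
            return f"<{self.below_threshold:g}"
        return f"{self.value:g}"


@dataclass
class ReferenceTable:
    """Validated collection of VOC features and per-origin statistics.

    Features are kept in canonical identifier order (A1, A2, ..., sorted by
    numeric suffix) so downstream feature matrices have a documented column
    ordering; the file's row order (grouped by chemical class) is not
    preserved in memory.
    """

    features: list[VocFeature]
    stats: dict[tuple[str, int], OriginStats]
    p_values: dict[str, PValue]
    provenance: str = ""
    #: file row order, kept only so write->load round-trips by identifier
    _row_order: list[str] = field(default_factory=list, repr=False)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def feature(self, feature_id: str) -> VocFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def mean_matrix(self) -> np.ndarray:
        """(3 origins x n_features) intensity means in canonical order."""
        return np.array(
            [[self.stats[(fid, o)].mean_intensity for fid in self.feature_ids]
             for o in range(len(ORIGINS))]
        )

    def sd_matrix(self) -> np.ndarray:
        """(3 origins x n_features) intensity SDs in canonical order."""
        return np.array(
            [[self.stats[(fid, o)].sd_intensity for fid in self.feature_ids]
             for o in range(len(ORIGINS))]
        )

    def validate(self, expected_features: int | None = None) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceValidationError(f"duplicate feature_id: {dup}")
        if expected_features is not None and len(ids) != expected_features:
            raise ReferenceValidationError(
                f"expected {expected_features} features, found {len(ids)}"
            )
        if expected_features is not None:
            want = {f"A{i}" for i in range(1, expected_features + 1)}
            if set(ids) != want:
                missing = sorted(want - set(ids))
                raise ReferenceValidationError(
                    f"feature identifiers do not cover A1..A{expected_features};"
                    f" missing {missing[:5]}"
                )
        for f in self.features:
            if f.chem_class not in CHEM_CLASSES:
                raise ReferenceValidationError(
                    f"{f.feature_id}: unknown chemical class {f.chem_class!r}"
                )
            for o in range(len(ORIGINS)):
                if (f.feature_id, o) not in self.stats:
                    raise ReferenceValidationError(
                        f"{f.feature_id}: missing statistics for origin "
                        f"{ORIGINS[o]}"
                    )
            if f.feature_id not in self.p_values:
                raise ReferenceValidationError(
                    f"{f.feature_id}: missing p-value"
                )
        if len(self.stats) != 3 * len(self.features):
            raise ReferenceValidationError(
                f"expected {3 * len(self.features)} stats entries, found "
                f"{len(self.stats)}"
            )
        for s in self.stats.values():
            if not (s.mean_intensity > 0):
                raise ReferenceValidationError(
                    f"{s.feature_id}/{ORIGINS[s.origin]}: mean must be > 0"
                )
            if s.sd_intensity < 0:
                raise ReferenceValidationError(
                    f"{s.feature_id}/{ORIGINS[s.origin]}: sd must be >= 0"
                )
        for p in self.p_values.values():
            if not (0 < p.value <= 1):
                raise ReferenceValidationError("p-value outside (0, 1]")
        self._validate_letter_consistency()

    def _validate_letter_consistency(self) -> None:
        # Two origins sharing a Duncan letter must not bracket a third origin
        # (strictly between them in mean) whose letter set is disjoint.
        for f in self.features:
            rows = [self.stats[(f.feature_id, o)] for o in range(len(ORIGINS))]
            for a in rows:
                for b in rows:
                    if a is b or not (set(a.duncan_letter) & set(b.duncan_letter)):
                        continue
                    lo, hi = sorted((a.mean_intensity, b.mean_intensity))
                    for c in rows:
                        if c is a or c is b:
                            continue
                        between = lo < c.mean_intensity < hi
                        disjoint = not (
                            set(c.duncan_letter)
                            & (set(a.duncan_letter) | set(b.duncan_letter))
                        )
                        if between and disjoint:
                            raise ReferenceValidationError(
                                f"{f.feature_id}: inconsistent Duncan letters"
                            )


def _canonical_sort(ids: list[str]) -> list[str]:
    return sorted(ids, key=lambda s: int(re.sub(r"\D", "", s) or 0))


def _parse_p(text: str) -> PValue:
    text = str(text).strip()
    if text.startswith("<"):
        bound = float(text[1:])
        return PValue(value=bound / 2.0, below_threshold=bound)
    return PValue(value=float(text))


def _default_fixture_path() -> Path:
    return Path(resources.files("kelptrace").joinpath("data/voc_reference.tsv"))


def load_reference_table(
    path: str | Path | None = None,
    expected_features: int | None = 115,
) -> ReferenceTable:
    """Load and validate the VOC reference table.

    Parameters
    ----------
    path
        Delimited table (TSV or CSV, sniffed from the header line).  Defaults
        to the packaged transcription of the published table.
    expected_features
        Enforce the feature count and A1..An identifier coverage; pass None
        to accept user tables of any size.
    """
    src = Path(path) if path is not None else _default_fixture_path()
    if not src.exists():
        raise FileNotFoundError(src)
    with open(src, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(src, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "odor_description"]
    if missing:
        raise ReferenceValidationError(f"missing columns: {missing}")

    features: list[VocFeature] = []
    stats: dict[tuple[str, int], OriginStats] = {}
    p_values: dict[str, PValue] = {}
    row_order: list[str] = []
    for idx, row in df.iterrows():
        fid = row["feature_id"].strip()
        if not fid:
            raise ReferenceValidationError(f"row {idx + 2}: empty feature_id")
        row_order.append(fid)

        def _num(col: str) -> float | None:
            cell = str(row.get(col, "")).strip()
            return float(cell) if cell else None

        odor = str(row.get("odor_description", "")).strip()
        features.append(
            VocFeature(
                feature_id=fid,
                compound_name=row["compound_name"].strip(),
                form=row["form"].strip(),
                chem_class=row["chem_class"].strip(),
                ri=_num("RI"),
                rt=_num("Rt_sec"),
                dt=_num("Dt_au"),
                odor_descriptors=tuple(
                    d.strip() for d in odor.split(",") if d.strip()
                ),
            )
        )
        for o, col in enumerate(_ORIGIN_COLS):
            try:
                mean = float(row[f"mean_{col}"])
                sd = float(row[f"sd_{col}"])
            except ValueError as exc:
                raise ReferenceValidationError(
                    f"{fid}: unparseable mean/sd cell for {col}: "
                    f"{row[f'mean_{col}']!r} +/- {row[f'sd_{col}']!r}"
                ) from exc
            stats[(fid, o)] = OriginStats(
                feature_id=fid,
                origin=o,
                mean_intensity=mean,
                sd_intensity=sd,
                duncan_letter=row[f"letter_{col}"].strip(),
            )
        try:
            p_values[fid] = _parse_p(row["p_value"])
        except ValueError as exc:
            raise ReferenceValidationError(
                f"{fid}: unparseable p-value {row['p_value']!r}"
            ) from exc

    order = _canonical_sort([f.feature_id for f in features])
    features.sort(key=lambda f: order.index(f.feature_id))
    table = ReferenceTable(
        features=features,
        stats=stats,
        p_values=p_values,
        provenance=str(src),
        _row_order=row_order,
    )
    table.validate(expected_features=expected_features)
    return table


def write_reference_table(table: ReferenceTable, path: str | Path) -> None:
    """Write a reference table back to TSV (lossless round-trip by id)."""
    rows = []
    order = table._row_order or table.feature_ids
    by_id = {f.feature_id: f for f in table.features}
    for fid in order:
        f = by_id[fid]
        rec: dict[str, object] = {
            "feature_id": f.feature_id,
            "compound_name": f.compound_name,
            "form": f.form,
            "chem_class": f.chem_class,
            "RI": "" if f.ri is None else f.ri,
            "Rt_sec": "" if f.rt is None else f.rt,
            "Dt_au": "" if f.dt is None else f.dt,
        }
        for o, col in enumerate(_ORIGIN_COLS):
            s = table.stats[(fid, o)]
            rec[f"mean_{col}"] = s.mean_intensity
            rec[f"sd_{col}"] = s.sd_intensity
            rec[f"letter_{col}"] = s.duncan_letter
        rec["p_value"] = str(table.p_values[fid])
        rec["odor_description"] = ", ".join(f.odor_descriptors)
        rows.append(rec)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def summarize_classes(table: ReferenceTable) -> dict[str, object]:
    """Count distinct compound species per chemical class.

    Monomer/dimer signals of one compound count as a single species;
    unidentified features are excluded from species counts but reported
    separately.
    """
    species: dict[str, set[str]] = {}
    identified_features = 0
    for f in table.features:
        if not f.identified:
            continue
        identified_features += 1
        species.setdefault(f.chem_class, set()).add(f.compound_name)
    counts = {cls: len(names) for cls, names in sorted(species.items())}
    return {
        "species_by_class": counts,
        "total_species": sum(counts.values()),
        "identified_features": identified_features,
        "unidentified_features": len(table.features) - identified_features,
        "total_features": len(table.features),
    }


def count_significant(table: ReferenceTable, alpha: float = 0.05) -> int:
    """Number of features whose printed ANOVA p-value satisfies p < alpha."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return sum(p.is_below(alpha) for p in table.p_values.values())
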