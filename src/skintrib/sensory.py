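"""Sensory questionnaire data: validation, profiles, wide/long conversion.

Panellists rate each material on six tactile attributes — slippery, soft,
rough, thick, greasy, pleasant — on a continuous 1-10 interval scale,
anchoring at least one material on each extreme grade per attribute.
The attribute vocabulary is closed; descriptive prose names (stickiness,
softness, ...) map onto it through :data:`~skintrib.synthgen.ATTRIBUTE_ALIASES`
without inverting any values.  Ratings are stored as real numbers since
panellists place marks on a continuous scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .synthgen import ATTRIBUTE_ALIASES, ATTRIBUTES

LONG_COLUMNS = ("panellist", "material", "attribute", "rating")


@dataclass
class ValidationReport:
    """Outcome of questionnaire validation: hard errors and soft warnings."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class SensoryTable:
    """Long-format panellist x material x attribute ratings."""

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"sensory table missing column(s): {missing}")
        df["attribute"] = (
            df["attribute"].astype(str).str.strip().str.lower()
            .map(lambda a: ATTRIBUTE_ALIASES.get(a, a))
        )
        unknown = sorted(set(df["attribute"]) - set(ATTRIBUTES))
        if unknown:
            raise ParseError(f"unknown attribute(s): {unknown}")
        dup = df.duplicated(subset=["panellist", "material", "attribute"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ParseError(
                "duplicate rating for "
                f"({first['panellist']}, {first['material']}, {first['attribute']})"
            )
        df["rating"] = df["rating"].astype(float)
        self.records = df[list(LONG_COLUMNS)].reset_index(drop=True)

    @property
    def panellists(self) -> list:
        return sorted(self.records["panellist"].unique())

    @property
    def materials(self) -> list:
        return sorted(self.records["material"].unique())

    def to_wide(self) -> pd.DataFrame:
        """One row per (panellist, material), attribute columns in fixed order."""
        wide = self.records.pivot(
            index=["panellist", "material"], columns="attribute", values="rating"
        )
        return wide.reindex(columns=list(ATTRIBUTES))

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "SensoryTable":
        long = (
            wide.reset_index()
            .melt(id_vars=["panellist", "material"], var_name="attribute",
                  value_name="rating")
            .dropna(subset=["rating"])
        )
        return cls(long)

    def attribute_means(self) -> pd.DataFrame:
        """Per-(panellist, material) means == the wide table (one rating each)."""
        return self.to_wide()


def validate_questionnaire(table: SensoryTable) -> ValidationReport:
    """Check scale bounds, completeness and the extremes anchoring rule.

    Bounds violations and missing (material, attribute) cells are errors;
    a panellist/attribute column that uses neither extreme grade (no
    rating within 0.5 of 1 or of 10) only warns, since imported human data
    may legitimately deviate from the anchoring instruction.
    """
    report = ValidationReport()
    df = table.records
    bad = df[(df["rating"] < 1.0) | (df["rating"] > 10.0)]
    for _, r in bad.iterrows():
        report.errors.append(
            f"rating {r['rating']} outside [1, 10] for "
            f"({r['panellist']}, {r['material']}, {r['attribute']})"
        )
    materials = table.materials
    for panellist, grp in df.groupby("panellist"):
        for attr in ATTRIBUTES:
            sub = grp[grp["attribute"] == attr]
            present = set(sub["material"])
            absent = sorted(set(materials) - present)
            if absent:
                report.errors.append(
                    f"{panellist}/{attr}: missing rating(s) for {absent}"
                )
                continue
            vals = sub["rating"].to_numpy()
            if not (np.any(vals <= 1.5) and np.any(vals >= 9.5)):
                report.warnings.append(
                    f"{panellist}/{attr}: extremes rule not met "
                    f"(range {vals.min():.1f}-{vals.max():.1f})"
                )
    return report


def radar_profile(table: SensoryTable, panellist: str) -> pd.DataFrame:
    """Attribute-ordered rating vectors of one panellist, per material.

    Rows are materials, columns the six attributes in canonical order —
    the data behind a radar chart.  Raises for an unknown panellist or a
    missing (material, attribute) cell.
    """
    sub = table.records[table.records["panellist"] == panellist]
    if sub.empty:
        raise ValidationError(f"unknown panellist {panellist!r}")
    wide = sub.pivot(index="material", columns="attribute", values="rating")
    wide = wide.reindex(columns=list(ATTRIBUTES))
    if wide.isna().any().any():
        holes = [
            (m, a) for m in wide.index for a in ATTRIBUTES
            if pd.isna(wide.loc[m, a])
        ]
        raise ValidationError(f"missing cells for panellist {panellist}: {holes}")
    return wide


def plot_radar(profile: pd.DataFrame, ax=None, title: str | None = None):
    """Radar chart of per-material attribute vectors (rows of ``profile``)."""
    import matplotlib.pyplot as plt

    angles = np.linspace(0, 2 * np.pi, len(ATTRIBUTES), endpoint=False)
    angles = np.concatenate([angles, angles[:1]])
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for material, row in profile.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = np.concatenate([vals, vals[:1]])
        ax.plot(angles, vals, label=str(material))
        ax.fill(angles, vals, alpha=0.08)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(ATTRIBUTES)
    ax.set_ylim(0, 10)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="small")
    return ax
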