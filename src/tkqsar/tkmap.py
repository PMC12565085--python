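"""TK-risk mapping: combine predicted bioavailability, VDss, and half-life.

Each chemical's predicted oral bioavailability (thresholds 30 % / 60 %), VDss
(0.6 / 5 L·kg⁻¹) and elimination half-life (4 h / 24 h) are assigned to
low/medium/high categories; a chemical is flagged as a TK concern when at
least one property is high (slow elimination, extensive tissue distribution,
or high systemic exposure). Half-life predictions come from an external model
and are consumed as an input column; chemicals lacking them are categorized on
the two available properties. Out-of-domain predictions are categorized but
marked, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import F_MULTICLASS, HALFLIFE_MULTICLASS, VDSS_MULTICLASS
from .errors import MissingPropertyError

HIGH = "high"
ABSENT = "absent"


@dataclass(frozen=True)
class TKProfile:
    chemical_id: str
    f_percent: float | None = None
    vdss: float | None = None
    halflife_h: float | None = None
    in_f_ad: bool = True
    in_vdss_ad: bool = True
    in_t12_ad: bool = True
    family: str = ""


def categorize_tk(p: TKProfile, require_all: bool = False) -> tuple[str, str, str]:
    """(vdss_cat, f_cat, t12_cat), each low/medium/high (or ``absent``).

    Values exactly at a threshold fall in the lower category ("high" is
    strictly greater), matching the discretization convention used for model
    training. With ``require_all`` a missing property raises
    ``MISSING_PROPERTY``; otherwise it is reported as ``absent``.
    """
    if require_all and None in (p.f_percent, p.vdss, p.halflife_h):
        raise MissingPropertyError(f"profile {p.chemical_id} lacks a TK property")
    vd = VDSS_MULTICLASS.label_of(p.vdss) if p.vdss is not None else ABSENT
    f = F_MULTICLASS.label_of(p.f_percent) if p.f_percent is not None else ABSENT
    t12 = (HALFLIFE_MULTICLASS.label_of(p.halflife_h)
           if p.halflife_h is not None else ABSENT)
    return vd, f, t12


def concern_flag(cats: tuple[str, str, str]) -> bool:
    """True iff at least one available TK category is high."""
    return HIGH in cats


def family_summary(profiles: list[TKProfile]) -> pd.DataFrame:
    """Per-family aggregation: counts, AD coverage, categories, flag fraction.

    Also appends an ``ALL`` row over every profile. ``pct_flagged`` counts all
    chemicals; ``pct_flagged_in_ad`` restricts both numerator and denominator
    to chemicals inside every available AD.
    """
    if not profiles:
        return pd.DataFrame(columns=[
            "family", "n", "n_in_f_ad", "n_in_vdss_ad", "n_in_t12_ad",
            "n_vdss_high", "n_f_high", "n_t12_high",
            "n_flagged", "pct_flagged", "pct_flagged_in_ad",
        ])
    rows = []
    families = sorted({p.family for p in profiles})
    for fam in families + ["ALL"]:
        group = [p for p in profiles if fam == "ALL" or p.family == fam]
        cats = {p.chemical_id: categorize_tk(p) for p in group}
        flagged = [p for p in group if concern_flag(cats[p.chemical_id])]
        in_ad = [p for p in group if p.in_f_ad and p.in_vdss_ad and p.in_t12_ad]
        flagged_in_ad = [p for p in in_ad if concern_flag(cats[p.chemical_id])]
        rows.append({
            "family": fam,
            "n": len(group),
            "n_in_f_ad": sum(p.in_f_ad for p in group),
            "n_in_vdss_ad": sum(p.in_vdss_ad for p in group),
            "n_in_t12_ad": sum(p.in_t12_ad for p in group),
            "n_vdss_high": sum(cats[p.chemical_id][0] == HIGH for p in group),
            "n_f_high": sum(cats[p.chemical_id][1] == HIGH for p in group),
            "n_t12_high": sum(cats[p.chemical_id][2] == HIGH for p in group),
            "n_flagged": len(flagged),
            "pct_flagged": 100.0 * len(flagged) / len(group),
            "pct_flagged_in_ad": (100.0 * len(flagged_in_ad) / len(in_ad)
                                  if in_ad else float("nan")),
        })
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[TKProfile]:
    """Build profiles from a table with columns id, f_percent, vdss,
    optional halflife_h / family / in_*_ad booleans."""
    out = []
    for row in df.itertuples(index=False):
        def opt(name):
            v = getattr(row, name, None)
            return None if v is None or pd.isna(v) else float(v)

        out.append(TKProfile(
            chemical_id=str(row.id),
            f_percent=opt("f_percent"),
            vdss=opt("vdss"),
            halflife_h=opt("halflife_h"),
            in_f_ad=bool(getattr(row, "in_f_ad", True)),
            in_vdss_ad=bool(getattr(row, "in_vdss_ad", True)),
            in_t12_ad=bool(getattr(row, "in_t12_ad", True)),
            family=str(getattr(row, "family", "") or ""),
        ))
    return out
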