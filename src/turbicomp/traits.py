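"""Species-level trait tables: element areas, composites, snout metrics.

Specimen rows carry per-element turbinal surface areas (length^2), skull
and snout linear measurements (length), and a diet / lifestyle label.
Elements follow the murine naming: nasoturbinal ``nt`` and maxilloturbinal
``mt`` anteriorly (respiratory), and lamina semicircularis ``ls``,
frontoturbinals ``ft1``/``ft2``, interturbinals ``it``/``it2`` and
ethmoturbinals ``etI``–``etIII`` posteriorly (olfactory).  ``ft2`` and
``it2`` occur only in a minority of taxa and are treated as absent (zero
contribution) when missing.

The nasoturbinal carries both respiratory and olfactory epithelium, so the
respiratory/olfactory partition is computed under an explicit
``nt_assignment`` switch; the total surface is invariant to it.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENT_COLUMNS",
    "RESPIRATORY_ELEMENTS",
    "OLFACTORY_ELEMENTS",
    "MEASUREMENT_COLUMNS",
    "DIETS",
    "LIFESTYLES",
    "validate_specimens",
    "species_average",
    "derive_composites",
    "attach_complexity",
]

RESPIRATORY_ELEMENTS = ("nt", "mt")
OLFACTORY_ELEMENTS = ("ls", "ft1", "ft2", "it", "it2", "etI", "etII", "etIII")
ELEMENT_COLUMNS = RESPIRATORY_ELEMENTS + OLFACTORY_ELEMENTS
MEASUREMENT_COLUMNS = ("SKL", "SNL", "SNW")
DIETS = ("omnivorous", "carnivorous", "vermivorous")
LIFESTYLES = ("terrestrial", "semi-fossorial")

_OPTIONAL_ELEMENTS = {"ft2", "it2"}
NtAssignment = Literal["respiratory", "olfactory"]


def validate_specimens(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, positivity and label vocabularies of a specimen table."""
    required = ["species", "specimen", *ELEMENT_COLUMNS, *MEASUREMENT_COLUMNS,
                "diet", "lifestyle"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    numeric = [*ELEMENT_COLUMNS, *MEASUREMENT_COLUMNS]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals <= 0) & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"column {col!r}: non-positive value at row(s) {list(bad[:5])}"
            )
        mandatory_nan = df.index[df[col].isna() & (col not in _OPTIONAL_ELEMENTS)]
        if col not in _OPTIONAL_ELEMENTS and len(mandatory_nan) == len(df) and len(df):
            raise ValueError(f"column {col!r} is entirely missing")
    bad_diet = sorted(set(df["diet"]) - set(DIETS))
    if bad_diet:
        raise ValueError(f"unknown diet label(s) {bad_diet}; allowed {DIETS}")
    bad_life = sorted(set(df["lifestyle"]) - set(LIFESTYLES))
    if bad_life:
        raise ValueError(f"unknown lifestyle label(s) {bad_life}; allowed {LIFESTYLES}")
    return df


def species_average(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse specimens to per-species arithmetic means on the raw scale.

    Numeric fields are averaged over the specimens where they are present
    (a missing optional element simply drops out of its own mean); diet and
    lifestyle must be consistent within a species.  Species with several
    specimens get ``n_specimens`` > 1 and, where an optional element was
    missing in some specimens, a note in ``averaging_flags``.
    """
    df = validate_specimens(records)
    numeric = [*ELEMENT_COLUMNS, *MEASUREMENT_COLUMNS]
    out_rows = []
    for sp, grp in df.groupby("species", sort=True):
        for label_col in ("diet", "lifestyle"):
            labels = set(grp[label_col])
            if len(labels) > 1:
                raise ValueError(
                    f"species {sp!r}: conflicting {label_col} labels {sorted(labels)}"
                )
        row = {"species": sp, "n_specimens": len(grp)}
        flags = []
        for col in numeric:
            present = grp[col].dropna()
            row[col] = float(present.mean()) if len(present) else np.nan
            if 0 < len(present) < len(grp):
                flags.append(f"{col}:mean over {len(present)}/{len(grp)} specimens")
        row["diet"] = grp["diet"].iloc[0]
        row["lifestyle"] = grp["lifestyle"].iloc[0]
        row["averaging_flags"] = "; ".join(flags)
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("species")


def derive_composites(
    species_means: pd.DataFrame, nt_assignment: NtAssignment = "respiratory"
) -> pd.DataFrame:
    """Derive surface-area composites and ratios from per-species element means.

    Respiratory and olfactory totals partition the overall total:
    ``RespiSA + OlfaSA = TotSA`` and ``RelatRespiSA + RelatOlfaSA = 1``
    under either nasoturbinal assignment; only where ``nt`` sits switches.
    """
    if nt_assignment not in ("respiratory", "olfactory"):
        raise ValueError(f"nt_assignment must be respiratory|olfactory, got {nt_assignment!r}")
    df = species_means.copy()
    elems = df.reindex(columns=ELEMENT_COLUMNS).astype(float).fillna(0.0)
    if (elems["mt"] <= 0).any():
        raise ValueError("maxilloturbinal (mt) area required for every species")
    olfa_core = elems[list(OLFACTORY_ELEMENTS)].sum(axis=1)
    if nt_assignment == "respiratory":
        respi = elems["nt"] + elems["mt"]
        olfa = olfa_core
    else:
        respi = elems["mt"]
        olfa = olfa_core + elems["nt"]
    tot = respi + olfa
    if (tot <= 0).any():
        raise ValueError("zero total turbinal surface area")
    df["RespiSA"] = respi
    df["OlfaSA"] = olfa
    df["TotSA"] = tot
    df["RelatRespiSA"] = respi / tot
    df["RelatOlfaSA"] = olfa / tot
    df["ratioOlfaRespi"] = olfa / respi
    df["RelatNT"] = elems["nt"] / tot
    df["RelatMT"] = elems["mt"] / tot
    df["relSNL"] = df["SNL"] / df["SKL"]
    df["relSNW"] = df["SNW"] / df["SKL"]
    df["nt_assignment"] = nt_assignment
    # natural-log versions of the allometric variables used in log-log fits
    for col in ("RespiSA", "OlfaSA", "TotSA", "SKL", "SNL", "SNW", "ratioOlfaRespi"):
        df[f"log{col}"] = np.log(df[col])
    return df


def attach_complexity(
    species_traits: pd.DataFrame, results: pd.DataFrame
) -> pd.DataFrame:
    """Join per-group complexity measurements onto the species trait table.

    `results` is tidy with columns ``species``, ``group`` in
    {respiratory, olfactory}, and any of ``CHAR``, ``CHNSI``, ``Db``.
    Output gains e.g. ``OlfaCHAR``/``RespiCHAR`` and, where both are
    present, ``ratioCHAR = OlfaCHAR / RespiCHAR`` (and similarly for Db).
    Missing one side leaves the ratio missing, never zero.
    """
    prefix = {"respiratory": "Respi", "olfactory": "Olfa"}
    bad = sorted(set(results["group"]) - set(prefix))
    if bad:
        raise ValueError(f"unknown complexity group label(s) {bad}; allowed {sorted(prefix)}")
    df = species_traits.copy()
    metrics = [c for c in ("CHAR", "CHNSI", "Db") if c in results.columns]
    for grp, pre in prefix.items():
        sub = results[results["group"] == grp].set_index("species")
        for m in metrics:
            df[f"{pre}{m}"] = sub[m].reindex(df.index)
    for m in metrics:
        o, r = f"Olfa{m}", f"Respi{m}"
        if o in df.columns and r in df.columns:
            df[f"ratio{m}"] = df[o] / df[r]
    return df
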