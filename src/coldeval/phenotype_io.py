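"""Reading, writing and derivation of evaluation-index tables.

Covers three jobs: loading delimited variety × index tables (with optional
replicate columns that are averaged), converting paired control/treated raw
measurements into recovery indices (SR = Ts/CKs, CRI = Tc/CKc, NRI = Tn/CKn),
and scoring leaf-withering fractions on the ordinal 1–9 damage scale.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    HIGHER_IS_BETTER,
    LOWER_IS_BETTER,
    DuplicateLabelError,
    IndexMatrix,
    PhenotypeError,
    PolarityError,
    RawMeasurements,
)

_REPLICATE_RE = re.compile(r"^(?P<base>.+)_r\d+$")

#: Default polarity of the five morphological recovery indices.
DEFAULT_MORPHOLOGICAL_POLARITY = {
    "LWD7": LOWER_IS_BETTER,
    "RLWD7": LOWER_IS_BETTER,
    "SR": HIGHER_IS_BETTER,
    "CRI": HIGHER_IS_BETTER,
    "NRI": HIGHER_IS_BETTER,
}


def load_polarity_config(path: str | Path) -> dict[str, str]:
    """Load a YAML mapping of index name → polarity (optionally with roles).

    Accepts either ``index: polarity`` entries or
    ``index: {polarity: ..., role: ...}`` blocks; roles are ignored here.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise PolarityError(f"{path}: polarity config must be a mapping")
    out: dict[str, str] = {}
    for name, entry in raw.items():
        out[str(name)] = str(entry["polarity"] if isinstance(entry, Mapping) else entry)
    return out


def _collapse_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average columns named ``<index>_r1 .. _rk`` into a single ``<index>``."""
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for col in df.columns:
        m = _REPLICATE_RE.match(str(col))
        base = m.group("base") if m else str(col)
        if base not in groups:
            groups[base] = []
            order.append(base)
        groups[base].append(col)
    out = {base: df[cols].mean(axis=1) if len(cols) > 1 else df[cols[0]] for base, cols in groups.items()}
    return pd.DataFrame(out, index=df.index)[order]


def load_index_table(
    path: str | Path,
    polarity_config: Mapping[str, str] | str | Path,
    *,
    sep: str | None = None,
    impute_missing: bool = False,
) -> IndexMatrix:
    """Read a delimited variety × index table into a validated ``IndexMatrix``.

    Parameters
    ----------
    path
        CSV/TSV file with a header row; first column holds variety labels.
        Replicate columns suffixed ``_r1 .. _rk`` are averaged.
    polarity_config
        Mapping of index name → polarity, or path to a YAML file with one.
    sep
        Field delimiter; inferred from the file when omitted.
    impute_missing
        When True, missing cells are filled with the per-index column mean
        (explicitly, never silently); when False (default) they are rejected.
    """
    if isinstance(polarity_config, (str, Path)):
        polarity_config = load_polarity_config(polarity_config)
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise PhenotypeError(f"{path}: no data rows/columns found")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise DuplicateLabelError(f"{path}: duplicate variety label(s): {dup}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise PhenotypeError(
                f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}"
            )
        df[col] = coerced
    df = _collapse_replicates(df)
    if df.isna().any().any():
        if impute_missing:
            df = df.fillna(df.mean())
        else:
            i, j = np.argwhere(df.isna().to_numpy())[0]
            raise PhenotypeError(
                f"{path}: missing cell at row {df.index[i]!r}, column {df.columns[j]!r} "
                "(pass impute_missing=True to mean-impute)"
            )
    missing_pol = [c for c in df.columns if c not in polarity_config]
    if missing_pol:
        raise PolarityError(f"{path}: no polarity configured for index(es): {missing_pol}")
    return IndexMatrix(df, {c: polarity_config[c] for c in df.columns})


def write_index_table(matrix: IndexMatrix, path: str | Path, *, precision: int = 6) -> None:
    """Write the canonical CSV form (variety label first, then index columns)."""
    matrix.data.to_csv(path, index_label="variety", float_format=f"%.{precision}g")


def score_lwd(withered_fraction: float, *, whole_plant: bool = False) -> int:
    """Score a withered leaf-area fraction on the ordinal 1–9 damage scale.

    Degrees: 1 = normal leaf (fraction 0); 3 = up to one quarter withered;
    5 = one quarter to one half; 7 = more than one half, short of total;
    9 = whole plant withered (fraction 1.0, or ``whole_plant=True``).
    Intervals are left-open/right-closed. Higher degree means worse damage.
    """
    f = float(withered_fraction)
    if not 0.0 <= f <= 1.0:
        raise PhenotypeError(f"withered fraction {f} outside [0, 1]")
    if whole_plant or f == 1.0:
        return 9
    if f == 0.0:
        return 1
    if f <= 0.25:
        return 3
    if f <= 0.5:
        return 5
    return 7


def compute_recovery_indices(
    control: Iterable[RawMeasurements],
    treated: Iterable[RawMeasurements],
) -> IndexMatrix:
    """Derive the five morphological evaluation indices from paired raw data.

    Per variety: SR = Ts/CKs (treated over control survival rate),
    CRI = Tc/CKc (chlorophyll recovery), NRI = Tn/CKn (nitrogen recovery),
    plus the treated plants' ordinal leaf-withering degrees LWD7 (day 7 of
    stress) and RLWD7 (day 7 of recovery growth).
    """
    ctrl = {m.variety_id: m for m in control}
    trt = {m.variety_id: m for m in treated}
    only_ctrl = sorted(set(ctrl) - set(trt))
    only_trt = sorted(set(trt) - set(ctrl))
    if only_ctrl or only_trt:
        raise PhenotypeError(
            f"unpaired varieties — control only: {only_ctrl}, treated only: {only_trt}"
        )
    rows = {}
    for vid in ctrl:  # preserves control insertion order
        c, t = ctrl[vid], trt[vid]
        ck_s = c.surviving_count / c.sown_count if c.sown_count else 0.0
        t_s = t.surviving_count / t.sown_count if t.sown_count else 0.0
        for label, denom in (("SR", ck_s), ("CRI", c.chlorophyll_reading), ("NRI", c.nitrogen_reading)):
            if denom == 0:
                raise ZeroDivisionError(
                    f"variety {vid!r}: zero control denominator for {label}"
                )
        rows[vid] = {
            "LWD7": float(score_lwd(t.withered_fraction_day7)),
            "RLWD7": float(score_lwd(t.withered_fraction_recovery7)),
            "SR": t_s / ck_s,
            "CRI": t.chlorophyll_reading / c.chlorophyll_reading,
            "NRI": t.nitrogen_reading / c.nitrogen_reading,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return IndexMatrix(df, dict(DEFAULT_MORPHOLOGICAL_POLARITY))
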