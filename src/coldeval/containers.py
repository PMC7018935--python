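"""In-memory containers for phenotype tables.

``IndexMatrix`` is the central data structure: a varieties × evaluation-indices
table (a pandas DataFrame) together with per-index polarity metadata saying
whether a larger value indicates a more tolerant plant (survival rate,
recovery indices) or a more damaged one (leaf-withering degree,
malondialdehyde content).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"
_POLARITIES = (HIGHER_IS_BETTER, LOWER_IS_BETTER)


class PhenotypeError(ValueError):
    """Base class for phenotype-table validation failures."""


class DuplicateLabelError(PhenotypeError):
    pass


class PolarityError(PhenotypeError):
    pass


@dataclass
class IndexMatrix:
    """Varieties × evaluation-indices matrix with polarity metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by variety id, one numeric column per evaluation index.
    polarity : dict
        Maps every column name to ``"higher_is_better"`` or
        ``"lower_is_better"``.

    Raises
    ------
    DuplicateLabelError
        If variety ids or index names repeat.
    PolarityError
        If any column lacks a polarity entry or carries an unknown flag.
    PhenotypeError
        If any cell is missing or non-finite.
    """

    data: pd.DataFrame
    polarity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise PhenotypeError("index matrix must contain at least one variety and one index")
        dup_v = df.index[df.index.duplicated()].unique().tolist()
        if dup_v:
            raise DuplicateLabelError(f"duplicate variety label(s): {dup_v}")
        dup_i = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_i:
            raise DuplicateLabelError(f"duplicate index label(s): {dup_i}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise PhenotypeError(f"non-numeric cell in index matrix: {exc}") from exc
        if not np.isfinite(values).all():
            bad = [
                (str(df.index[i]), str(df.columns[j]))
                for i, j in zip(*np.where(~np.isfinite(values)))
            ]
            raise PhenotypeError(f"non-finite cell(s) at (variety, index): {bad[:5]}")
        missing = [c for c in df.columns if c not in self.polarity]
        if missing:
            raise PolarityError(f"no polarity configured for index(es): {missing}")
        bad_flags = {c: p for c, p in self.polarity.items() if p not in _POLARITIES}
        if bad_flags:
            raise PolarityError(
                f"unknown polarity flag(s) {bad_flags}; expected one of {_POLARITIES}"
            )
        self.data = df.astype(float)

    @property
    def variety_ids(self) -> list[str]:
        return [str(v) for v in self.data.index]

    @property
    def index_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def polarity_signs(self) -> np.ndarray:
        """Per-column sign: +1 where higher is better, −1 where lower is."""
        return np.array(
            [1.0 if self.polarity[c] == HIGHER_IS_BETTER else -1.0 for c in self.data.columns]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndexMatrix):
            return NotImplemented
        return self.data.equals(other.data) and self.polarity == {
            c: other.polarity[c] for c in other.data.columns
        }


@dataclass
class RawMeasurements:
    """Raw seedling measurements for one variety in one group (control or treated).

    ``sown_count``/``surviving_count`` come from the survival assay (30 grains
    per variety in the original design); meter readings are already averaged
    over replicates; withered fractions are the fraction of leaf area withered
    on day 7 of stress and after 7 days of recovery growth.
    """

    variety_id: str
    sown_count: int
    surviving_count: int
    chlorophyll_reading: float
    nitrogen_reading: float
    withered_fraction_day7: float = 0.0
    withered_fraction_recovery7: float = 0.0

    def __post_init__(self) -> None:
        if self.sown_count < 0 or self.surviving_count < 0:
            raise PhenotypeError(f"{self.variety_id}: counts must be non-negative")
        if self.surviving_count > self.sown_count:
            raise PhenotypeError(
                f"{self.variety_id}: surviving_count {self.surviving_count} exceeds "
                f"sown_count {self.sown_count}"
            )
        if self.chlorophyll_reading < 0 or self.nitrogen_reading < 0:
            raise PhenotypeError(f"{self.variety_id}: meter readings must be non-negative")
        for name in ("withered_fraction_day7", "withered_fraction_recovery7"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise PhenotypeError(f"{self.variety_id}: {name}={f} outside [0, 1]")
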