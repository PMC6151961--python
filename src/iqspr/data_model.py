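"""Core typed containers and CSV I/O shared by every modelling stage.

The package works on two aligned tables: a compounds × descriptors matrix
(:class:`DescriptorTable`) and a per-compound table of the two modelled drug
properties (:class:`PropertyTable`) — chromatographic lipophilicity ``log k_w``
and inhibitory activity ``log K_i`` (K_i in nM). Descriptors carry a kind flag
(continuous / integer / binary) because the downstream filters and the
mixed-integer model inversion treat the kinds differently.

CSV conventions: comma-separated, UTF-8, mandatory header row, '.' decimal
separator. Missing values are rejected, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("continuous", "integer", "binary")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


def infer_kind(column: np.ndarray) -> str:
    """Classify a descriptor column as binary, integer or continuous.

    All values in {0, 1} -> binary; all whole numbers -> integer; else
    continuous. Deterministic and independent of row order.
    """
    col = np.asarray(column, dtype=float)
    if np.all(np.isin(col, (0.0, 1.0))):
        return "binary"
    if np.all(col == np.round(col)):
        return "integer"
    return "continuous"


@dataclass
class DescriptorTable:
    """Compounds × molecular-descriptor matrix with per-descriptor kinds."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        n, p = self.values.shape
        if len(self.compound_ids) != n or len(self.descriptor_names) != p:
            raise ValidationError(
                f"matrix is {n}x{p} but {len(self.compound_ids)} compound ids "
                f"and {len(self.descriptor_names)} descriptor names were given"
            )
        dup = _duplicates(self.compound_ids)
        if dup:
            raise ValidationError(f"duplicate compound ids: {sorted(dup)}")
        dup = _duplicates(self.descriptor_names)
        if dup:
            raise ValidationError(f"duplicate descriptor names: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            rows, cols = np.nonzero(~np.isfinite(self.values))
            cells = [
                (self.compound_ids[r], self.descriptor_names[c])
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(f"missing/non-finite values at {cells}")
        if not self.kinds:
            self.kinds = [infer_kind(self.values[:, j]) for j in range(p)]
        if len(self.kinds) != p:
            raise ValidationError("kinds length does not match descriptor count")
        for name, kind in zip(self.descriptor_names, self.kinds):
            if kind not in KINDS:
                raise ValidationError(f"unknown kind {kind!r} for {name}")
        for j, (name, kind) in enumerate(zip(self.descriptor_names, self.kinds)):
            col = self.values[:, j]
            if kind == "binary" and not np.all(np.isin(col, (0.0, 1.0))):
                raise ValidationError(f"binary descriptor {name} has values outside {{0,1}}")
            if kind == "integer" and not np.all(col == np.round(col)):
                raise ValidationError(f"integer descriptor {name} has fractional values")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.descriptor_names,
        )

    def subset(self, names: list[str]) -> "DescriptorTable":
        """Column subset (e.g. the GA-selected descriptors), order of `names`."""
        pos = {n: j for j, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValidationError(f"unknown descriptors: {missing}")
        idx = [pos[n] for n in names]
        return DescriptorTable(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=self.values[:, idx],
            kinds=[self.kinds[j] for j in idx],
        )

    def reorder(self, compound_ids: list[str]) -> "DescriptorTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in pos]
        if missing:
            raise ValidationError(f"unknown compound ids: {missing}")
        idx = [pos[c] for c in compound_ids]
        return DescriptorTable(
            compound_ids=list(compound_ids),
            descriptor_names=list(self.descriptor_names),
            values=self.values[idx],
            kinds=list(self.kinds),
        )


@dataclass
class PropertyTable:
    """Per-compound drug properties: log k_w (lipophilicity), log K_i (activity)."""

    compound_ids: list[str]
    logkw: np.ndarray
    logKi: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.logkw = np.asarray(self.logkw, dtype=float)
        self.logKi = np.asarray(self.logKi, dtype=float)
        n = len(self.compound_ids)
        if self.logkw.shape != (n,) or self.logKi.shape != (n,):
            raise ValidationError("property columns do not match compound id count")
        dup = _duplicates(self.compound_ids)
        if dup:
            raise ValidationError(f"duplicate compound ids: {sorted(dup)}")
        if not (np.all(np.isfinite(self.logkw)) and np.all(np.isfinite(self.logKi))):
            raise ValidationError("properties must be finite")

    @property
    def Y(self) -> np.ndarray:
        """n × 2 response matrix, columns (logkw, logKi)."""
        return np.column_stack([self.logkw, self.logKi])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"logkw": self.logkw, "logKi": self.logKi},
            index=pd.Index(self.compound_ids, name="compound_id"),
        )

    def select(self, compound_ids: list[str]) -> "PropertyTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in pos]
        if missing:
            raise ValidationError(f"unknown compound ids: {missing}")
        idx = [pos[c] for c in compound_ids]
        return PropertyTable(list(compound_ids), self.logkw[idx], self.logKi[idx])


@dataclass(frozen=True)
class ReferenceProperties:
    """Target property values for model inversion (a reference drug)."""

    logkw_ref: float
    logKi_ref: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.logkw_ref) and np.isfinite(self.logKi_ref)):
            raise ValidationError("reference properties must be finite")


@dataclass
class RetentionSeries:
    """Isocratic retention data: organic-modifier fraction phi vs log k."""

    phi: np.ndarray
    logk: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.logk = np.asarray(self.logk, dtype=float)
        if self.phi.shape != self.logk.shape or self.phi.size < 2:
            raise ValidationError("need >= 2 (phi, log k) pairs of equal length")
        if np.any((self.phi < 0) | (self.phi > 1)):
            raise ValidationError("phi must lie in [0, 1]")
        if len(np.unique(self.phi)) != self.phi.size:
            raise ValidationError("phi values must be distinct")


# ---------------------------------------------------------------------------
# CSV I/O


def read_descriptor_table(path, kinds_path=None) -> DescriptorTable:
    """Read a descriptor CSV (first column: compound id; header: names).

    An optional kinds CSV maps descriptor -> kind; kinds absent from it (or
    when no kinds file is given) are inferred: all values in {0,1} -> binary,
    all whole -> integer, else continuous.
    """
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        cell = (df.index[rows[0]], df.columns[cols[0]])
        raise ValidationError(f"missing value at {cell} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = _first_non_numeric(df)
        raise ValidationError(f"non-numeric cell at {bad} in {path}") from exc
    names = [str(c) for c in df.columns]
    kinds_map: dict[str, str] = {}
    if kinds_path is not None:
        kdf = pd.read_csv(kinds_path)
        kinds_map = dict(zip(kdf.iloc[:, 0].astype(str), kdf.iloc[:, 1].astype(str)))
    kinds = [
        kinds_map.get(name, infer_kind(values[:, j])) for j, name in enumerate(names)
    ]
    return DescriptorTable([str(i) for i in df.index], names, values, kinds)


def write_descriptor_table(table: DescriptorTable, path, kinds_path=None) -> None:
    table.to_dataframe().to_csv(path)
    if kinds_path is not None:
        pd.DataFrame(
            {"descriptor": table.descriptor_names, "kind": table.kinds}
        ).to_csv(kinds_path, index=False)


def read_property_table(path) -> PropertyTable:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in ("logkw", "logKi") if c not in df.columns]
    if missing:
        raise ValidationError(f"property CSV lacks columns {missing}")
    return PropertyTable(
        [str(i) for i in df.index],
        df["logkw"].to_numpy(dtype=float),
        df["logKi"].to_numpy(dtype=float),
    )


def write_property_table(table: PropertyTable, path) -> None:
    table.to_dataframe().to_csv(path)


def align(desc: DescriptorTable, props: PropertyTable) -> tuple[DescriptorTable, PropertyTable]:
    """Align the two tables on compound id.

    The property-table order is canonical: the descriptor table is reordered
    to it, which makes downstream splits deterministic.
    """
    have = set(desc.compound_ids)
    missing = [c for c in props.compound_ids if c not in have]
    if missing:
        raise ValidationError(f"compound ids absent from descriptor table: {missing}")
    return desc.reorder(props.compound_ids), props


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _first_non_numeric(df: pd.DataFrame):
    for i, row in enumerate(df.itertuples(index=False)):
        for j, v in enumerate(row):
            try:
                float(v)
            except (TypeError, ValueError):
                return (df.index[i], df.columns[j])
    return None
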