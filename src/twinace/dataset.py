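"""Twin-pair data container and CSV input/output.

The canonical layout is one family (twin pair) per row: a zygosity label
(``MZ``/``DZ``), per-pair age, per-twin sex, and for every trait two columns
``<trait>1`` / ``<trait>2`` holding twin 1's and twin 2's scores.  Missing
phenotype cells are permitted and preserved; families with one missing co-twin
still contribute their observed member to full-information likelihoods.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import EmptyInputError, SchemaError

MZ = "MZ"
DZ = "DZ"

#: canonical metadata columns of the wide layout
_META = ["family_id", "zygosity", "age", "sex1", "sex2"]


class TwinDataset:
    """Wide-format twin data: one record per family.

    Parameters
    ----------
    frame : pandas.DataFrame
        Wide table with columns ``family_id``, ``zygosity`` (``"MZ"``/``"DZ"``),
        ``age`` (years, shared within pair), ``sex1``/``sex2`` (0 = male,
        1 = female) and ``<trait>1``/``<trait>2`` per trait.
    traits : sequence of str
        Ordered trait names; identical across families by construction.
    """

    def __init__(self, frame: pd.DataFrame, traits):
        traits = list(traits)
        missing = [c for c in _META if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        for t in traits:
            for suf in ("1", "2"):
                if t + suf not in frame.columns:
                    raise SchemaError(f"missing phenotype column: {t + suf}")
        bad = ~frame["zygosity"].isin([MZ, DZ])
        if bad.any():
            raise SchemaError(
                f"{int(bad.sum())} row(s) with zygosity outside {{MZ, DZ}}"
            )
        cols = _META + [t + s for t in traits for s in ("1", "2")]
        self._frame = frame[cols].reset_index(drop=True)
        self.traits = traits
        #: rows rejected during parsing (set by load_dataset)
        self.n_rejected = 0

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def n_families(self) -> int:
        return len(self._frame)

    def n_pairs(self, zygosity: str | None = None) -> int:
        if zygosity is None:
            return self.n_families
        return int((self._frame["zygosity"] == zygosity).sum())

    def subset(self, zygosity: str) -> "TwinDataset":
        sub = self._frame[self._frame["zygosity"] == zygosity]
        return TwinDataset(sub, self.traits)

    def trait_pairs(self, trait: str, zygosity: str | None = None) -> np.ndarray:
        """(n, 2) array of twin-1/twin-2 scores for one trait (NaN = missing)."""
        f = self._frame
        if zygosity is not None:
            f = f[f["zygosity"] == zygosity]
        return f[[trait + "1", trait + "2"]].to_numpy(float)

    def phenotype_matrix(self, traits=None, zygosity: str | None = None) -> np.ndarray:
        """(n, 2k) array ordered [traits of twin 1, traits of twin 2]."""
        traits = list(traits) if traits is not None else self.traits
        f = self._frame
        if zygosity is not None:
            f = f[f["zygosity"] == zygosity]
        cols = [t + "1" for t in traits] + [t + "2" for t in traits]
        return f[cols].to_numpy(float)

    def individuals(self) -> pd.DataFrame:
        """Long view, one row per twin (columns: family_id, zygosity, twin,
        age, sex, one column per trait)."""
        rows = []
        for twin in (1, 2):
            sub = pd.DataFrame(
                {
                    "family_id": self._frame["family_id"],
                    "zygosity": self._frame["zygosity"],
                    "twin": twin,
                    "age": self._frame["age"],
                    "sex": self._frame[f"sex{twin}"],
                }
            )
            for t in self.traits:
                sub[t] = self._frame[f"{t}{twin}"]
            rows.append(sub)
        return pd.concat(rows, ignore_index=True)

    def with_phenotypes(self, values: dict) -> "TwinDataset":
        """Copy with phenotype columns replaced; `values` maps column name
        (e.g. ``grit1``) to a vector."""
        frame = self._frame.copy()
        for col, v in values.items():
            frame[col] = np.asarray(v, float)
        return TwinDataset(frame, self.traits)

    def swap_twin_order(self, mask=None) -> "TwinDataset":
        """Copy with twin 1 and twin 2 exchanged (for invariance checks)."""
        frame = self._frame.copy()
        if mask is None:
            mask = np.ones(len(frame), bool)
        mask = np.asarray(mask, bool)
        pairs = [("sex1", "sex2")] + [(t + "1", t + "2") for t in self.traits]
        for c1, c2 in pairs:
            a, b = frame[c1].to_numpy().copy(), frame[c2].to_numpy().copy()
            frame[c1] = np.where(mask, b, a)
            frame[c2] = np.where(mask, a, b)
        return TwinDataset(frame, self.traits)

    # ------------------------------------------------------------------ #
    # I/O
    # ------------------------------------------------------------------ #
    def write_csv(self, path) -> None:
        # %.17g guarantees binary64 round-trip through the text file
        self._frame.to_csv(path, index=False, float_format="%.17g")

    def to_long(self) -> pd.DataFrame:
        return self.individuals()

    @classmethod
    def from_long(cls, long: pd.DataFrame, traits, twin_col: str = "twin"):
        """Build from one-twin-per-row data keyed by ``family_id``.

        Twin order within family follows the ``twin_col`` values (1/2) when
        present, else order of appearance.
        """
        long = long.copy()
        if twin_col not in long.columns:
            long[twin_col] = long.groupby("family_id").cumcount() + 1
        if (long.groupby("family_id")[twin_col].count() > 2).any():
            raise SchemaError("a family has more than 2 twins")
        rows = {}
        for fam, grp in long.groupby("family_id", sort=False):
            rec = {
                "family_id": fam,
                "zygosity": grp["zygosity"].iloc[0],
                "age": grp["age"].iloc[0],
            }
            for _, r in grp.iterrows():
                i = int(r[twin_col])
                rec[f"sex{i}"] = r.get("sex", np.nan)
                for t in traits:
                    rec[f"{t}{i}"] = r.get(t, np.nan)
            rows[fam] = rec
        frame = pd.DataFrame(list(rows.values()))
        for c in _META + [t + s for t in traits for s in ("1", "2")]:
            if c not in frame.columns:
                frame[c] = np.nan
        return cls(frame, traits)


def _read_schema(schema):
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    return dict(schema)


def load_dataset(path, schema) -> TwinDataset:
    """Read a twin table from CSV according to a column-mapping schema.

    Parameters
    ----------
    path : str or Path
        CSV file, UTF-8, header row required.
    schema : mapping or path to a YAML file
        Keys: ``traits`` (mapping trait -> {twin1: col, twin2: col}, or a list
        of trait names using the canonical ``<trait>1``/``<trait>2`` columns),
        ``zygosity`` (column name, default ``zygosity``), ``zygosity_levels``
        (mapping of file labels onto ``MZ``/``DZ``), ``age``, ``sex``
        ({twin1: col, twin2: col}), ``sex_levels`` (labels for male/female,
        default 0/1 already coded), ``family_id`` (optional),
        ``format``: ``wide`` (default) or ``long``.

    Rows whose zygosity label maps to neither MZ nor DZ are rejected; their
    count is reported on the returned dataset (``n_rejected``) and via a
    warning.  Missing phenotype cells are preserved as missing.
    """
    schema = _read_schema(schema)
    try:
        # round_trip parsing: text written at %.17g reloads bit-exactly
        raw = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty input file: {path}") from None
    if raw.empty:
        raise EmptyInputError(f"no data rows in: {path}")

    if schema.get("format", "wide") == "long":
        return _load_long(raw, schema)

    zcol = schema.get("zygosity", "zygosity")
    acol = schema.get("age", "age")
    sex = schema.get("sex", {"twin1": "sex1", "twin2": "sex2"})
    traits_cfg = schema["traits"]
    if isinstance(traits_cfg, (list, tuple)):
        traits_cfg = {t: {"twin1": t + "1", "twin2": t + "2"} for t in traits_cfg}

    for name, col in [("zygosity", zcol), ("age", acol)]:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col} ({name})")
    for t, m in traits_cfg.items():
        for k in ("twin1", "twin2"):
            if m[k] not in raw.columns:
                raise SchemaError(f"missing mandatory column: {m[k]} (trait {t})")

    levels = schema.get("zygosity_levels", {MZ: MZ, DZ: DZ})
    label_of = {str(v): k for k, v in levels.items()}
    zyg = raw[zcol].astype(str).map(label_of)
    keep = zyg.isin([MZ, DZ])
    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} row(s) with unparseable zygosity")
    raw = raw[keep].reset_index(drop=True)
    zyg = zyg[keep].reset_index(drop=True)

    sex_levels = schema.get("sex_levels")

    def code_sex(col):
        if col not in raw.columns:
            return np.full(len(raw), np.nan)
        v = raw[col]
        if sex_levels:
            return v.map({sex_levels["male"]: 0, sex_levels["female"]: 1}).to_numpy(float)
        return v.to_numpy(float)

    frame = pd.DataFrame(
        {
            "family_id": raw[schema["family_id"]]
            if schema.get("family_id") in raw.columns
            else np.arange(len(raw)),
            "zygosity": zyg,
            "age": raw[acol].to_numpy(float),
            "sex1": code_sex(sex["twin1"]),
            "sex2": code_sex(sex["twin2"]),
        }
    )
    for t, m in traits_cfg.items():
        frame[t + "1"] = raw[m["twin1"]].to_numpy(float)
        frame[t + "2"] = raw[m["twin2"]].to_numpy(float)

    ds = TwinDataset(frame, list(traits_cfg))
    ds.n_rejected = n_rejected
    return ds


def _load_long(raw, schema):
    traits = schema["traits"]
    if isinstance(traits, dict):
        traits = list(traits)
    needed = ["family_id", "zygosity", "age"]
    for col in needed:
        if schema.get(col, col) not in raw.columns:
            raise SchemaError(f"missing mandatory column: {schema.get(col, col)}")
    ren = {schema.get(c, c): c for c in needed + ["sex", "twin"] + list(traits)}
    raw = raw.rename(columns=ren)
    levels = schema.get("zygosity_levels", {MZ: MZ, DZ: DZ})
    label_of = {str(v): k for k, v in levels.items()}
    raw["zygosity"] = raw["zygosity"].astype(str).map(label_of)
    keep = raw["zygosity"].isin([MZ, DZ])
    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} row(s) with unparseable zygosity")
    ds = TwinDataset.from_long(raw[keep], traits)
    ds.n_rejected = n_rejected
    return ds
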