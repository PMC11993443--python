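"""Core in-memory containers: expression matrices and probe→gene maps.

An :class:`ExpressionMatrix` is a features × samples grid of log2-scale
intensities together with the metadata the downstream analysis needs to
interpret it: whether rows are probes or gene symbols, which platform the
values came from, and which preprocessing steps (mean-centering, z-scaling)
have already been applied.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ProbeGeneMap"]

_FEATURE_KINDS = ("gene", "probe")


@dataclasses.dataclass
class ExpressionMatrix:
    """Feature × sample matrix of log2-scale expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features (probes or gene symbols), columns are sample ids.
        Values must be finite numbers.
    feature_kind : {"gene", "probe"}
        What the row index holds.
    platform : str
        Free-text platform tag (e.g. a microarray chip name).
    centered, zscaled : bool
        Preprocessing flags; set by :func:`immunesig.io.mean_center` and
        :func:`immunesig.io.zscale`.
    """

    data: pd.DataFrame
    feature_kind: str = "gene"
    platform: str = ""
    centered: bool = False
    zscaled: bool = False

    def __post_init__(self) -> None:
        if self.feature_kind not in _FEATURE_KINDS:
            raise ValueError(
                f"feature_kind must be one of {_FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (features x samples)")
        dup_feat = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_feat):
            raise ValueError(f"duplicate feature ids: {list(map(str, dup_feat[:5]))}")
        dup_samp = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_samp):
            raise ValueError(f"duplicate sample ids: {list(map(str, dup_samp[:5]))}")
        try:
            values = self.data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"expression values must be numeric: {exc}") from exc
        if not np.isfinite(values).all():
            bad = int((~np.isfinite(values)).sum())
            raise ValueError(f"expression values must be finite ({bad} non-finite cells)")
        self.data = self.data.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def features(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, features: Iterable[str]) -> "ExpressionMatrix":
        """Return a matrix restricted to ``features`` (order preserved)."""
        features = list(features)
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return self.replace(data=self.data.loc[features])

    def replace(self, **updates) -> "ExpressionMatrix":
        """Copy with selected fields replaced."""
        kwargs = dict(
            data=self.data,
            feature_kind=self.feature_kind,
            platform=self.platform,
            centered=self.centered,
            zscaled=self.zscaled,
        )
        kwargs.update(updates)
        return ExpressionMatrix(**kwargs)


class ProbeGeneMap:
    """Many-to-one mapping of probe ids to gene symbols."""

    def __init__(self, mapping: Mapping[str, str] | pd.Series):
        if isinstance(mapping, pd.Series):
            mapping = mapping.to_dict()
        self._map: dict[str, str] = {str(k): str(v) for k, v in mapping.items()}
        if not self._map:
            raise ValueError("probe->gene map is empty")

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, probe: str) -> bool:
        return probe in self._map

    def gene_of(self, probe: str) -> str:
        return self._map[probe]

    @property
    def probes(self) -> list[str]:
        return list(self._map)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self._map.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self._map, name="gene_symbol").rename_axis("probe_id")

    @classmethod
    def read_tsv(cls, path) -> "ProbeGeneMap":
        """Read a two-column tab-delimited annotation (probe_id, gene_symbol)."""
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if frame.shape[1] < 2:
            raise ValueError("probe annotation needs two columns: probe_id, gene_symbol")
        probes, genes = frame.iloc[:, 0], frame.iloc[:, 1]
        if probes.duplicated().any():
            dups = probes[probes.duplicated()].tolist()
            raise ValueError(f"probe mapped to more than one gene: {dups[:5]}")
        return cls(dict(zip(probes, genes)))

    def write_tsv(self, path) -> None:
        self.as_series().reset_index().to_csv(path, sep="\t", index=False)
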