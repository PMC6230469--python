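"""Delimited-text readers/writers and the run configuration.

Expression files hold genes as rows and cells as columns, with a header row
of cell identifiers and the gene identifier in the first column; the
delimiter (comma or tab) is autodetected.  Capture-time tables are
two-column files ``cell_id,capture_time``.  Chain sample files are CSV with
one row per stored draw (iteration, log-likelihood, log hyperparameters and
the 1-based cell index at every position) preceded by ``#``-prefixed
metadata lines, so a file round-trips into an identical
:class:`~pseudorank.sampler.ChainSamples`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InvalidInputError
from .model import ExpressionMatrix
from .sampler import ChainSamples

__all__ = [
    "read_expression",
    "write_expression",
    "read_capture_times",
    "write_capture_times",
    "write_samples",
    "read_samples",
    "RunConfig",
]

PathLike = Union[str, Path]


def _sniff_sep(path: PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise InvalidInputError(f"{path}: empty file")


def read_expression(
    path: PathLike, capture_times: Optional[PathLike] = None
) -> ExpressionMatrix:
    """Read a genes-by-cells expression matrix (CSV or TSV)."""
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise InvalidInputError(f"{path}: {exc}") from None
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")
    values = df.to_numpy(dtype=float)
    ct = None
    cell_ids = [str(c) for c in df.columns]
    if capture_times is not None:
        table = read_capture_times(capture_times)
        missing = [c for c in cell_ids if c not in table.index]
        if missing:
            raise InvalidInputError(
                f"capture-time table misses cells: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        ct = table.loc[cell_ids].to_numpy()
    return ExpressionMatrix(values, list(df.index.astype(str)), cell_ids, ct)


def write_expression(expr: ExpressionMatrix, path: PathLike, sep: str = ",") -> None:
    df = pd.DataFrame(
        expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
        columns=expr.cell_ids,
    )
    df.to_csv(path, sep=sep, float_format="%.12g")


def read_capture_times(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if df.shape[1] < 2:
        raise InvalidInputError(
            f"{path}: expected columns cell_id and capture_time"
        )
    s = df.set_index(df.columns[0])[df.columns[1]]
    s.index = s.index.astype(str)
    return s


def write_capture_times(expr: ExpressionMatrix, path: PathLike) -> None:
    if expr.capture_times is None:
        raise InvalidInputError("expression matrix has no capture times")
    pd.DataFrame(
        {"cell_id": expr.cell_ids, "capture_time": expr.capture_times}
    ).to_csv(path, index=False)


def write_samples(samples: ChainSamples, path: PathLike) -> None:
    """Write a chain's thinned draws as a commented CSV file."""
    T = samples.n_cells
    meta = dict(samples.meta)
    meta["move_proposed"] = [int(x) for x in samples.move_proposed]
    meta["move_accepted"] = [int(x) for x in samples.move_accepted]
    meta["param_proposed"] = int(samples.param_proposed)
    meta["param_accepted"] = int(samples.param_accepted)
    meta["param_proposed_post"] = int(samples.param_proposed_post)
    meta["param_accepted_post"] = int(samples.param_accepted_post)
    df = pd.DataFrame(
        {
            "iteration": samples.iterations,
            "log_lik": samples.log_lik,
            "log_sigma_w2": samples.log_sigma_w2,
            "log_l": samples.log_l,
        }
    )
    for j in range(T):
        df[f"pos_{j + 1}"] = samples.orders[:, j] + 1  # 1-based on disk
    with open(path, "w") as fh:
        fh.write("# pseudorank chain samples\n")
        fh.write(f"# meta: {json.dumps(meta)}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_samples(path: PathLike) -> ChainSamples:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta:"):
                meta = json.loads(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    pos_cols = [c for c in df.columns if c.startswith("pos_")]
    if not pos_cols:
        raise InvalidInputError(f"{path}: no position columns found")
    orders = df[pos_cols].to_numpy(dtype=np.int32) - 1
    return ChainSamples(
        orders=orders,
        log_lik=df["log_lik"].to_numpy(),
        log_sigma_w2=df["log_sigma_w2"].to_numpy(),
        log_l=df["log_l"].to_numpy(),
        iterations=df["iteration"].to_numpy(dtype=np.int64),
        move_proposed=np.asarray(meta.pop("move_proposed", [0] * 5), dtype=np.int64),
        move_accepted=np.asarray(meta.pop("move_accepted", [0] * 5), dtype=np.int64),
        param_proposed=int(meta.pop("param_proposed", 0)),
        param_accepted=int(meta.pop("param_accepted", 0)),
        param_proposed_post=int(meta.pop("param_proposed_post", 0)),
        param_accepted_post=int(meta.pop("param_accepted_post", 0)),
        meta=meta,
    )


@dataclass
class RunConfig:
    """Flat, serializable configuration of a sampling run."""

    expression: Optional[str] = None
    capture_times: Optional[str] = None
    out_dir: str = "."
    mode: str = "geodesic"
    n_chains: int = 3
    n_iterations: int = 100_000
    thinning: int = 10
    burn_in: Optional[int] = None
    seed: int = 0
    active_moves: tuple = (1, 2, 3, 4)
    p5: float = 0.002
    gamma: Optional[float] = None
    alpha: float = 1.0
    prior_parametrization: str = "sigma_w2"
    minicluster: bool = False
    minicluster_fraction: float = 0.125
    minicluster_min: int = 5
    gene_filter: str = "none"  # none | anova | mean_variance
    n_keep_genes: int = 100
    reversal_anchor: str = "capture_times"  # capture_times | none | gene:<id>
    restrict_start: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.active_moves, list):
            cfg.active_moves = tuple(cfg.active_moves)
        return cfg

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: PathLike) -> None:
        data = dataclasses.asdict(self)
        data["active_moves"] = list(self.active_moves)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
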