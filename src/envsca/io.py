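"""Readers, writers and run configuration.

Series travel as long-format CSV with columns ``series_id``, ``time_index``
(contiguous integers per series) and ``state``.  Fitted models are stored as
JSON; floating-point values survive the round trip bit-exactly because the
encoder emits shortest-round-trip decimal representations of binary64.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

from .classify import GroupModel
from .series import CategoricalSeries
from .smb import SMBModel
from .spectral import EnvelopeScalings

__all__ = [
    "RunConfig",
    "ModelFile",
    "read_series_csv",
    "write_series_csv",
    "windows_by_percentile",
    "write_model",
    "read_model",
    "features_to_frame",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

REQUIRED_COLUMNS = ("series_id", "time_index", "state")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults for every field.

    ``bandwidth`` is either the string ``"sqrt"`` (use ``floor(sqrt(T))``)
    or an explicit positive integer.  ``reference_state=None`` means the
    last element of the state space.
    """

    bandwidth: object = "sqrt"
    kernel: str = "modified_daniell"
    reference_state: object = None
    kappa_grid: tuple = tuple(np.round(np.arange(11) / 10, 1))
    select_prop: float = 1.0
    method: str = "envsca"
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self):
        if self.bandwidth != "sqrt":
            if not isinstance(self.bandwidth, int) or self.bandwidth < 1:
                raise ValueError(
                    "bandwidth must be 'sqrt' or a positive integer, "
                    f"got {self.bandwidth!r}"
                )
        if self.kernel not in ("modified_daniell", "daniell"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0.0 < self.select_prop <= 1.0:
            raise ValueError("select_prop must lie in (0, 1]")
        if self.method not in ("env", "sca", "envsca", "smb-tvd", "smb-kl", "smb-ch"):
            raise ValueError(f"unknown method {self.method!r}")
        grid = np.asarray(self.kappa_grid, dtype=float)
        if grid.size == 0 or ((grid < 0) | (grid > 1)).any():
            raise ValueError("kappa_grid must be a nonempty subset of [0, 1]")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log_level {self.log_level!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {sorted(unknown)} "
                f"(known keys: {sorted(known)})"
            )
        d = dict(d)
        if "kappa_grid" in d:
            d["kappa_grid"] = tuple(d["kappa_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def resolve_bandwidth(self, T: int) -> int:
        if self.bandwidth == "sqrt":
            return int(np.floor(np.sqrt(T)))
        return int(self.bandwidth)


# ---------------------------------------------------------------------------
# series CSV


def read_series_csv(
    path,
    state_space: tuple | None = None,
    reference_state=None,
) -> list[CategoricalSeries]:
    """Read long-format series CSV into a list of categorical series.

    The parse is order-insensitive (rows are sorted by series id and time
    index); time indices must be contiguous per series from their minimum.
    If ``state_space`` is not declared it is inferred as the sorted union of
    observed states across all series (and logged) — note that a state seen
    only at prediction time is then a hard error, since the model assumes
    every category is observed across all series.
    """
    df = pd.read_csv(path, dtype={"series_id": str, "state": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    if df["state"].str.contains(",").any():
        bad = df.loc[df["state"].str.contains(","), "state"].iloc[0]
        raise ValueError(
            f"state label {bad!r} contains a comma; commas in labels are not supported"
        )
    if state_space is None:
        state_space = tuple(sorted(df["state"].unique()))
        logger.info("state space inferred from data: %s", list(state_space))
    else:
        state_space = tuple(state_space)
        unknown = set(df["state"].unique()) - set(state_space)
        if unknown:
            raise ValueError(
                f"state(s) {sorted(unknown)} not in the declared state space "
                f"{list(state_space)}"
            )
    out = []
    for sid, grp in df.sort_values(["series_id", "time_index"]).groupby(
        "series_id", sort=True
    ):
        t = grp["time_index"].to_numpy()
        gaps = np.flatnonzero(np.diff(t) != 1)
        if gaps.size:
            raise ValueError(
                f"series {sid!r}: time_index not contiguous at position "
                f"{int(gaps[0]) + 1} (index jumps {t[gaps[0]]} -> {t[gaps[0] + 1]})"
            )
        out.append(
            CategoricalSeries(
                values=grp["state"].tolist(),
                state_space=state_space,
                reference_state=reference_state,
                series_id=sid,
            )
        )
    return out


def write_series_csv(series: list[CategoricalSeries], path) -> None:
    rows = []
    for s in series:
        for lbl in s.state_space:
            if "," in str(lbl):
                raise ValueError(
                    f"state label {lbl!r} contains a comma; not representable"
                )
        for t, v in enumerate(s.values):
            rows.append({"series_id": s.series_id, "time_index": t, "state": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def windows_by_percentile(
    series: CategoricalSeries, lo: float = 0.4, hi: float = 0.9
) -> CategoricalSeries:
    """Trim a series to the index window ``floor(lo*T) .. ceil(hi*T)-1``.

    The defaults retain the 40th-90th percentile stretch used for hypnogram
    analysis, dropping the nonstationary sleep-onset and waking portions.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    T = series.T
    start = int(np.floor(lo * T))
    stop = int(np.ceil(hi * T))
    vals = series.values[start:stop]
    if len(vals) < 4:
        raise ValueError(
            f"window [{lo}, {hi}) of series {series.series_id!r} keeps only "
            f"{len(vals)} observations; need at least 4"
        )
    return CategoricalSeries(
        values=vals,
        state_space=series.state_space,
        reference_state=series.reference_state,
        series_id=series.series_id,
    )


# ---------------------------------------------------------------------------
# model files


@dataclass(frozen=True)
class ModelFile:
    """Serializable container for a fitted model plus its data contract.

    Holds either an envelope/scalings :class:`GroupModel` or an
    :class:`SMBModel`, together with the state space, reference category,
    smoothing settings, and the length ``T_grid`` whose Fourier grid the
    model's frequencies live on.
    """

    method: str
    state_space: tuple
    reference_state: object
    bandwidth: object  # "sqrt" or int
    kernel: str
    T_grid: int
    group_model: GroupModel | None = None
    smb_model: SMBModel | None = None
    loo_rate: float | None = None

    def __post_init__(self):
        if (self.group_model is None) == (self.smb_model is None):
            raise ValueError(
                "exactly one of group_model / smb_model must be provided"
            )


def write_model(model: ModelFile, path) -> None:
    d = {
        "format_version": MODEL_FORMAT_VERSION,
        "method": model.method,
        "state_space": list(model.state_space),
        "reference_state": model.reference_state,
        "bandwidth": model.bandwidth,
        "kernel": model.kernel,
        "T_grid": int(model.T_grid),
        "loo_rate": model.loo_rate,
    }
    if model.group_model is not None:
        gm = model.group_model
        d["kind"] = "envsca"
        d["group_labels"] = list(gm.group_labels)
        d["n_per_group"] = list(gm.n_per_group)
        d["freqs"] = gm.freqs.tolist()
        d["Lambda"] = gm.Lambda.tolist()
        d["Gamma"] = gm.Gamma.tolist()
        d["kappa"] = gm.kappa
        d["selected_env"] = gm.selected_env.tolist()
        d["selected_sca"] = gm.selected_sca.tolist()
    else:
        sm = model.smb_model
        d["kind"] = "smb"
        d["smb_kind"] = sm.kind
        d["theta"] = sm.theta
        d["group_labels"] = list(sm.group_labels)
        d["means_real"] = sm.means.real.tolist()
        d["means_imag"] = sm.means.imag.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh)


def read_model(path) -> ModelFile:
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is not valid JSON: {exc}") from exc
    version = d.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has format version {version!r}; this build "
            f"reads version {MODEL_FORMAT_VERSION}"
        )
    common = dict(
        method=d["method"],
        state_space=tuple(d["state_space"]),
        reference_state=d["reference_state"],
        bandwidth=d["bandwidth"],
        kernel=d["kernel"],
        T_grid=d["T_grid"],
        loo_rate=d["loo_rate"],
    )
    if d["kind"] == "envsca":
        gm = GroupModel(
            group_labels=tuple(d["group_labels"]),
            Lambda=np.asarray(d["Lambda"], dtype=float),
            Gamma=np.asarray(d["Gamma"], dtype=float),
            n_per_group=tuple(d["n_per_group"]),
            freqs=np.asarray(d["freqs"], dtype=float),
            kappa=d["kappa"],
            selected_env=np.asarray(d["selected_env"], dtype=int),
            selected_sca=np.asarray(d["selected_sca"], dtype=int),
        )
        return ModelFile(group_model=gm, **common)
    if d["kind"] == "smb":
        sm = SMBModel(
            group_labels=tuple(d["group_labels"]),
            means=np.asarray(d["means_real"], dtype=float)
            + 1j * np.asarray(d["means_imag"], dtype=float),
            kind=d["smb_kind"],
            theta=d["theta"],
        )
        return ModelFile(smb_model=sm, **common)
    raise ValueError(f"model file {path} has unknown kind {d['kind']!r}")


# ---------------------------------------------------------------------------
# feature export


def features_to_frame(
    series_ids: list, feats: list[EnvelopeScalings]
) -> pd.DataFrame:
    """Long table of features: series_id, freq, lambda, gamma_1..gamma_{m-1}."""
    rows = []
    for sid, f in zip(series_ids, feats):
        p = f.gam.shape[0]
        for k in range(f.K):
            row = {"series_id": sid, "freq": f.freqs[k], "lambda": f.lam[k]}
            for j in range(p):
                row[f"gamma_{j + 1}"] = f.gam[j, k]
            rows.append(row)
    return pd.DataFrame(rows)
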