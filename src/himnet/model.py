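"""Model-style front end for the multiplex dynamics analysis.

:class:`MultiplexDynamics` is constructed from a :class:`MultiplexSeries`;
``fit()`` runs the two-step pipeline (project every snapshot, extract the
anchored HIM distance series, score each series with increment entropy and
mean/variance changepoints) and returns a
:class:`MultiplexDynamicsResults` carrying the series, the indicator
values and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import MultiplexSeries
from .him import HIMParams
from .indicators import (
    ChangepointConfig,
    IncEntParams,
    crops_sweep,
    increment_entropy,
    pelt_meanvar,
)
from .multiplex import (
    DistanceSeries,
    distance_series_d1,
    distance_series_d1_mean,
    distance_series_d2,
    distance_series_d3,
)

__all__ = ["MultiplexDynamics", "MultiplexDynamicsResults", "stable_segmentation"]


def stable_segmentation(sweep: list[dict]) -> tuple[int, ...]:
    """The segmentation optimal over the widest penalty sub-interval of a
    CROPS sweep (ties broken toward larger penalties, i.e. fewer points)."""
    if not sweep:
        return ()
    widths = [rec["penalty_interval"][1] - rec["penalty_interval"][0] for rec in sweep]
    best = max(range(len(sweep)), key=lambda k: (widths[k], sweep[k]["penalty_interval"][0]))
    return tuple(sweep[best]["changepoints"])


class MultiplexDynamics:
    """Two-step dynamics analysis of a multiplex network time series."""

    def __init__(
        self,
        series: MultiplexSeries,
        him_params: HIMParams | None = None,
        collapsed_mode: str = "auto",
    ):
        self.series = series
        self.him_params = him_params or HIMParams()
        self.collapsed_mode = collapsed_mode

    @classmethod
    def from_snapshots(cls, snapshots, timestamps=(), **kwargs) -> "MultiplexDynamics":
        return cls(MultiplexSeries(tuple(snapshots), tuple(timestamps)), **kwargs)

    def fit(
        self,
        incent_params: IncEntParams | None = None,
        cp_config: ChangepointConfig | None = None,
    ) -> "MultiplexDynamicsResults":
        """Compute all distance series and their dynamics indicators."""
        s = self.series
        tau = s.tau
        incent_params = incent_params or IncEntParams()
        if cp_config is None:
            cp_config = ChangepointConfig(
                penalty_range=(2.0 * math.log(tau), 10.0 * math.log(tau))
            )
        d1 = [
            distance_series_d1(s, i, self.him_params) for i in range(s.n_layers)
        ]
        d1_mean = distance_series_d1_mean(s, self.him_params)
        d2 = distance_series_d2(s, self.him_params, self.collapsed_mode)
        d3 = (
            distance_series_d3(s, self.him_params) if s.n_layers >= 2 else None
        )
        all_series: dict[str, DistanceSeries] = {ds.label(): ds for ds in d1}
        all_series["d1mean"] = d1_mean
        all_series["d2"] = d2
        if d3 is not None:
            all_series["d3"] = d3
        incent = {
            name: (
                increment_entropy(ds.values, incent_params)
                if ds.tau >= incent_params.m + 2
                else float("nan")  # too short for a single word window
            )
            for name, ds in all_series.items()
        }
        changepoints: dict[str, dict] = {}
        for name in ("d2", "d3"):
            if name not in all_series:
                continue
            values = all_series[name].values
            if cp_config.penalty_range is not None:
                sweep = crops_sweep(values, cp_config)
                changepoints[name] = {
                    "sweep": sweep,
                    "stable": stable_segmentation(sweep),
                }
            else:
                res = pelt_meanvar(values, cp_config)
                changepoints[name] = {
                    "sweep": [
                        {
                            "penalty_interval": (res.penalty, res.penalty),
                            "changepoints": res.changepoints,
                            "cost": res.cost,
                            "n_changepoints": res.n_changepoints,
                        }
                    ],
                    "stable": res.changepoints,
                }
        return MultiplexDynamicsResults(
            model=self,
            series=all_series,
            incent=incent,
            changepoints=changepoints,
            incent_params=incent_params,
            cp_config=cp_config,
        )


@dataclass
class MultiplexDynamicsResults:
    """Fitted dynamics indicators for one multiplex series."""

    model: MultiplexDynamics
    series: dict[str, DistanceSeries]
    incent: dict[str, float]
    changepoints: dict[str, dict]
    incent_params: IncEntParams
    cp_config: ChangepointConfig

    @property
    def d2(self) -> DistanceSeries:
        return self.series["d2"]

    @property
    def d3(self) -> DistanceSeries:
        return self.series["d3"]

    def d1(self, layer_name: str) -> DistanceSeries:
        return self.series[f"d1[{layer_name}]"]

    def incent_table(self) -> pd.DataFrame:
        rows = [
            {"series": name, "incent_bits": val} for name, val in self.incent.items()
        ]
        return pd.DataFrame(rows)

    def series_frame(self) -> pd.DataFrame:
        """All distance series as a tidy DataFrame (t, timestamp, series, value)."""
        frames = []
        for name, ds in self.series.items():
            frames.append(
                pd.DataFrame(
                    {
                        "t": np.arange(1, ds.tau + 1),
                        "timestamp": ds.timestamps,
                        "series": name,
                        "value": ds.values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            "Multiplex dynamics analysis",
            "===========================",
            f"snapshots (tau): {s.tau}   layers (lambda): {s.n_layers}   "
            f"nodes (nu): {len(s.node_labels)}",
            f"HIM xi: {self.model.him_params.xi}   IncEnt m={self.incent_params.m}, "
            f"R={self.incent_params.R} ({self.incent_params.scale} scale)",
            "",
            "Increment entropy (bits):",
        ]
        for name, val in self.incent.items():
            lines.append(f"  {name:12s} {val:6.2f}")
        for name, cp in self.changepoints.items():
            lines.append("")
            lines.append(f"Changepoints of {name} (mean/variance PELT, CROPS sweep):")
            for rec in cp["sweep"]:
                lo, hi = rec["penalty_interval"]
                pts = ", ".join(str(i) for i in rec["changepoints"]) or "none"
                lines.append(f"  beta in [{lo:6.2f}, {hi:6.2f}] -> {pts}")
            stable = ", ".join(str(i) for i in cp["stable"]) or "none"
            lines.append(f"  most stable segmentation: {stable}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "incent": dict(self.incent),
            "changepoints": {
                name: {
                    "stable": list(cp["stable"]),
                    "sweep": [
                        {
                            "penalty_interval": list(rec["penalty_interval"]),
                            "changepoints": list(rec["changepoints"]),
                            "cost": rec["cost"],
                        }
                        for rec in cp["sweep"]
                    ],
                }
                for name, cp in self.changepoints.items()
            },
            "series": {name: ds.values.tolist() for name, ds in self.series.items()},
        }
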