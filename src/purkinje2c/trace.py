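"""Sampled simulation output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """Uniformly sampled channels (times in ms, voltages in mV, Ca/Na/K in mM).

    ``dt_ms`` is the sample interval (integration step x output stride).
    """

    dt_ms: float
    channels: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("channels have unequal lengths")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) * self.dt_ms

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def v_soma(self) -> np.ndarray:
        return self.channels["v_soma"]

    @property
    def v_dend(self) -> np.ndarray:
        return self.channels["v_dend"]

    def window(self, t0_ms: float, t1_ms: float) -> "Trace":
        """Sub-trace covering [t0, t1]."""
        i0 = max(0, int(np.ceil(t0_ms / self.dt_ms)))
        i1 = min(self.n_samples, int(np.floor(t1_ms / self.dt_ms)) + 1)
        return Trace(
            dt_ms=self.dt_ms,
            channels={k: v[i0:i1] for k, v in self.channels.items()},
            meta=dict(self.meta, t_offset_ms=i0 * self.dt_ms),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t_ms})
        for k, v in self.channels.items():
            df[k] = v
        return df

    def to_csv(self, path) -> None:
        """Comma-separated, '.' decimal, header row; times ms, voltages mV."""
        with open(path, "w") as fh:
            fh.write(f"# purkinje2c trace; dt_ms={self.dt_ms!r}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for part in first.lstrip("# ").strip().split(";"):
                    if "=" in part:
                        key, val = part.split("=", 1)
                        meta[key.strip()] = val.strip()
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        t = df["t_ms"].to_numpy()
        dt = float(meta.get("dt_ms", t[1] - t[0] if len(t) > 1 else 1.0))
        channels = {
            c: df[c].to_numpy(dtype=float) for c in df.columns if c != "t_ms"
        }
        return cls(dt_ms=dt, channels=channels)
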