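"""Small shared result containers (1D profiles / series with error estimates)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProfileSeries:
    """Generic 1D series: density vs z, S_CD vs carbon, ACF vs lag, g(r) vs r."""

    x: np.ndarray
    y: np.ndarray
    yerr: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.yerr is not None:
            self.yerr = np.asarray(self.yerr, dtype=float)

    def to_frame(self):
        import pandas as pd

        data = {"x": self.x, "y": self.y}
        if self.yerr is not None:
            data["yerr"] = self.yerr
        return pd.DataFrame(data)
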