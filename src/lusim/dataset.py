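"""RF trace container: (sweep position, element, time sample) + metadata.

In memory the traces live in an :class:`xarray.DataArray` so dimensions
stay named; on disk they go into an HDF5 file with a single "rf" dataset
and the acquisition metadata as attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import xarray as xr

__all__ = ["RFDataset"]


@dataclass
class RFDataset:
    """Acquired RF traces with the metadata imaging needs.

    ``rf`` has dims (sweep, element, sample).  ``attrs`` must carry at
    least dt, f0, n_elements, pitch, aperture_size, focus_depth and c_ref
    for the imaging chain to reconstruct geometry; provenance keys
    (variant, G, seeds, config) ride along.
    """

    rf: xr.DataArray
    attrs: dict = field(default_factory=dict)

    @classmethod
    def from_array(cls, traces: np.ndarray, dt: float, **attrs) -> "RFDataset":
        n_sweep, n_elem, n_samp = traces.shape
        da = xr.DataArray(
            traces,
            dims=("sweep", "element", "sample"),
            coords={"time": ("sample", (np.arange(n_samp) + 1) * dt)},
        )
        attrs = {"dt": dt, **attrs}
        return cls(rf=da, attrs=attrs)

    @property
    def n_sweeps(self) -> int:
        return self.rf.sizes["sweep"]

    @property
    def n_elements(self) -> int:
        return self.rf.sizes["element"]

    @property
    def n_samples(self) -> int:
        return self.rf.sizes["sample"]

    @property
    def dt(self) -> float:
        return float(self.attrs["dt"])

    @property
    def times(self) -> np.ndarray:
        return self.rf.coords["time"].values

    @property
    def values(self) -> np.ndarray:
        return self.rf.values

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rf", data=self.rf.values)
            for k, v in self.attrs.items():
                if isinstance(v, (dict, list, tuple)):
                    f.attrs[k] = json.dumps(v)
                else:
                    f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "RFDataset":
        with h5py.File(path, "r") as f:
            traces = f["rf"][...]
            attrs = {}
            for k, v in f.attrs.items():
                if isinstance(v, bytes):
                    v = v.decode()
                if isinstance(v, str) and v[:1] in "[{":
                    try:
                        v = json.loads(v)
                    except json.JSONDecodeError:
                        pass
                attrs[k] = v
        dt = float(attrs["dt"])
        return cls.from_array(traces, dt, **{k: v for k, v in attrs.items() if k != "dt"})
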