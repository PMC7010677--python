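"""HDF5 container for segmented datasets.

One group per split (train/validation/test); per-split stacked arrays
``measurement``, ``voluntary_gt``, ``shifted_target``, ``tremor`` of shape
``(n_segments, window)`` plus per-segment ``subject_id`` strings and the
scalar ``offset`` / ``rate_hz`` attributes.
"""

from __future__ import annotations

import h5py
import numpy as np

from .synthetic_data import VOLUNTARY_OFFSET, DatasetSplit, LabeledSegment

__all__ = ["save_dataset", "load_dataset"]

_SPLITS = ("train", "validation", "test")


def save_dataset(path, data: DatasetSplit) -> None:
    with h5py.File(path, "w") as f:
        for split in _SPLITS:
            segments: list[LabeledSegment] = getattr(data, split)
            g = f.create_group(split)
            if not segments:
                continue
            g.create_dataset("measurement", data=np.stack([s.measurement for s in segments]))
            g.create_dataset("voluntary_gt", data=np.stack([s.voluntary_gt for s in segments]))
            g.create_dataset(
                "shifted_target", data=np.stack([s.shifted_target for s in segments])
            )
            if all(s.tremor is not None for s in segments):
                g.create_dataset("tremor", data=np.stack([s.tremor for s in segments]))
            g.create_dataset(
                "subject_id",
                data=np.array([s.subject_id for s in segments], dtype="S16"),
            )
            g.attrs["offset"] = segments[0].offset
            g.attrs["rate_hz"] = segments[0].rate_hz


def load_dataset(path) -> DatasetSplit:
    parts = {}
    with h5py.File(path, "r") as f:
        for split in _SPLITS:
            segments = []
            g = f[split]
            if "measurement" in g:
                meas = g["measurement"][...]
                gt = g["voluntary_gt"][...]
                tgt = g["shifted_target"][...]
                tremor = g["tremor"][...] if "tremor" in g else [None] * len(meas)
                sids = [s.decode() for s in g["subject_id"][...]]
                offset = float(g.attrs.get("offset", VOLUNTARY_OFFSET))
                rate = float(g.attrs.get("rate_hz", 100.0))
                for i in range(len(meas)):
                    segments.append(
                        LabeledSegment(
                            measurement=meas[i],
                            voluntary_gt=gt[i],
                            shifted_target=tgt[i],
                            subject_id=sids[i],
                            tremor=None if tremor[i] is None else tremor[i],
                            offset=offset,
                            rate_hz=rate,
                        )
                    )
            parts[split] = segments
    return DatasetSplit(**parts)
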