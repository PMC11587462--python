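"""On-disk formats for pipeline stages.

The epoch container is a directory holding a binary array store
(``data.npy``, epoch x channel x time in microvolts), a delimited trial
table (``trials.tsv``), the channel layout (``channels.tsv``) and a YAML
sidecar with sampling metadata and provenance.  Binned data and
permutation products are NumPy ``.npz`` archives; behavioral and factor
tables are plain TSV.  An import hook for standard raw-EEG formats can
be registered behind :func:`read_raw_epochs` without touching the rest
of the package.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .containers import BinnedData, EpochsVolume

__all__ = ["save_epochs", "load_epochs", "save_binned", "load_binned",
           "register_raw_reader", "read_raw_epochs"]

FLOAT_FORMAT = "%.10g"


def save_epochs(outdir, epochs: EpochsVolume, trials: pd.DataFrame,
                behavioral: Optional[pd.DataFrame] = None,
                provenance: Optional[dict] = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "data.npy", epochs.data)
    trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    pd.DataFrame({"channel": epochs.ch_names,
                  "x": epochs.ch_pos[:, 0], "y": epochs.ch_pos[:, 1]}
                 ).to_csv(outdir / "channels.tsv", sep="\t", index=False,
                          float_format=FLOAT_FORMAT)
    meta = {
        "sfreq": float(epochs.sfreq),
        "tmin": float(epochs.tmin),
        "n_epochs": int(epochs.n_epochs),
        "average_referenced": bool(epochs.average_referenced),
        "baseline_corrected": bool(epochs.baseline_corrected),
        "units": "uV",
    }
    if provenance:
        meta["provenance"] = provenance
    with open(outdir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    if behavioral is not None:
        behavioral.to_csv(outdir / "behavioral.tsv", sep="\t",
                          float_format=FLOAT_FORMAT)
    return outdir


def load_epochs(indir) -> tuple[EpochsVolume, pd.DataFrame, Optional[pd.DataFrame]]:
    indir = Path(indir)
    data = np.load(indir / "data.npy")
    trials = pd.read_csv(indir / "trials.tsv", sep="\t")
    channels = pd.read_csv(indir / "channels.tsv", sep="\t")
    with open(indir / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    epochs = EpochsVolume(
        data=data, sfreq=float(meta["sfreq"]), tmin=float(meta["tmin"]),
        ch_names=tuple(channels["channel"]),
        ch_pos=channels[["x", "y"]].to_numpy(),
        average_referenced=bool(meta.get("average_referenced", False)),
        baseline_corrected=bool(meta.get("baseline_corrected", False)))
    behavioral = None
    if (indir / "behavioral.tsv").exists():
        behavioral = pd.read_csv(indir / "behavioral.tsv", sep="\t",
                                 index_col="participant")
    return epochs, trials, behavioral


def save_binned(path, binned: BinnedData) -> Path:
    path = Path(path)
    np.savez(
        path, scheme=binned.scheme, values=binned.values, counts=binned.counts,
        participants=np.asarray(binned.participants, dtype=object),
        bin_labels=np.asarray(binned.bin_labels, dtype=object),
        conditions=np.asarray(binned.conditions, dtype=object),
        sfreq=binned.sfreq, times=binned.times,
        ch_names=np.asarray(binned.ch_names, dtype=object),
        ch_pos=binned.ch_pos if binned.ch_pos is not None else np.empty((0, 2)))
    return path


def load_binned(path) -> BinnedData:
    with np.load(path, allow_pickle=True) as z:
        return BinnedData(
            scheme=str(z["scheme"]), values=z["values"], counts=z["counts"],
            participants=tuple(z["participants"].tolist()),
            bin_labels=tuple(z["bin_labels"].tolist()),
            conditions=tuple(z["conditions"].tolist()),
            sfreq=float(z["sfreq"]), times=z["times"],
            ch_names=tuple(z["ch_names"].tolist()),
            ch_pos=z["ch_pos"] if z["ch_pos"].size else None)


# --- optional raw-EEG import hook -------------------------------------------

_RAW_READERS: dict[str, Callable[..., tuple[EpochsVolume, pd.DataFrame]]] = {}


def register_raw_reader(suffix: str, reader: Callable) -> None:
    """Register an adapter turning a raw recording into (epochs, trials).

    Readers for BDF/EDF/FIF built on an established i/o library can be
    plugged in here; the rest of the pipeline is agnostic to the source.
    """
    _RAW_READERS[suffix.lower()] = reader


def read_raw_epochs(path, **kwargs) -> tuple[EpochsVolume, pd.DataFrame]:
    suffix = Path(path).suffix.lower()
    if suffix not in _RAW_READERS:
        raise KeyError(f"no raw reader registered for {suffix!r}; "
                       f"known: {sorted(_RAW_READERS)}")
    return _RAW_READERS[suffix](path, **kwargs)
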