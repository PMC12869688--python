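"""On-disk formats: recordings, channel tables, clinical tables, maps.

Recordings travel as a flat float32 binary matrix plus a JSON sidecar
(rate, channel metadata, units); channel tables as TSV; clinical tables as
CSV; maps and stacks as ``.npz`` containers with axis metadata, alongside
tidy TSV exports (subject, channel, frequency, value).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CLINICAL_COLUMNS, GroundTruth
from .types import ChannelInfo, CohortStack, RawRecording, SpatioSpectralMap

CHANNEL_TABLE_COLUMNS = ["name", "device", "contact_index", "cs_offset"]
CLINICAL_TABLE_COLUMNS = ["subject_id", "age", "years_dx"] + CLINICAL_COLUMNS


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write samples as float32 binary with a JSON sidecar; returns the .bin path."""
    path = Path(path)
    bin_path = path.with_suffix(".bin")
    rec.samples.astype(np.float32).tofile(bin_path)
    sidecar = {
        "rate_hz": rec.rate_hz,
        "units": "uV",
        "dtype": "float32",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "subject_id": rec.subject_id,
        "site": rec.site,
        "channels": [{"name": c.name, "device": c.device,
                      "contact_index": c.contact_index, "cs_offset": c.cs_offset}
                     for c in rec.channels],
    }
    bin_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return bin_path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path).with_suffix(".bin")
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=np.float32).reshape(meta["n_channels"], meta["n_samples"])
    channels = [ChannelInfo(c["name"], c["device"], c["contact_index"], c.get("cs_offset"))
                for c in meta["channels"]]
    return RawRecording(data.astype(float), meta["rate_hz"], channels,
                        subject_id=meta.get("subject_id", ""), site=meta.get("site", ""))


def write_channel_table(rec: RawRecording, path: str | Path) -> None:
    rows = [{"name": c.name, "device": c.device, "contact_index": c.contact_index,
             "cs_offset": "" if c.cs_offset is None else c.cs_offset}
            for c in rec.channels]
    pd.DataFrame(rows, columns=CHANNEL_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_channel_table(path: str | Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        cs = r.get("cs_offset")
        cs = None if pd.isna(cs) or cs == "" else int(cs)
        out.append(ChannelInfo(str(r["name"]), str(r["device"]), int(r["contact_index"]), cs))
    return out


def write_clinical_table(clin: pd.DataFrame, path: str | Path) -> None:
    clin[CLINICAL_TABLE_COLUMNS].to_csv(path, index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    def enc(x):
        return None if x is None else np.asarray(x).tolist()
    payload = {"template": enc(gt.template), "latents": enc(gt.latents),
               "cluster_labels": enc(gt.cluster_labels),
               "coupled_pairs": [list(p) for p in gt.coupled_pairs]}
    Path(path).write_text(json.dumps(payload))


def save_stack(stack: CohortStack, path: str | Path) -> None:
    np.savez_compressed(path, data=stack.data, freqs=stack.freqs,
                        subject_ids=np.array(stack.subject_ids),
                        channels=np.array(stack.channels), kind=stack.kind)


def load_stack(path: str | Path) -> CohortStack:
    with np.load(path, allow_pickle=False) as z:
        return CohortStack(z["data"], [str(s) for s in z["subject_ids"]],
                           [str(c) for c in z["channels"]], z["freqs"], str(z["kind"]))


def map_to_tidy(m: SpatioSpectralMap, subject: str = "") -> pd.DataFrame:
    nc, nf = m.shape
    return pd.DataFrame({
        "subject": subject,
        "channel": np.repeat(m.channels, nf),
        "frequency_hz": np.tile(m.freqs, nc),
        "value": m.values.ravel(),
    })


def stack_to_tidy(stack: CohortStack) -> pd.DataFrame:
    frames = [map_to_tidy(stack.subject_map(i), stack.subject_ids[i])
              for i in range(stack.n_subjects)]
    return pd.concat(frames, ignore_index=True)


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
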