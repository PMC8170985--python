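"""CSV history files and the JSON run manifest.

One file per quantity with a fixed column schema; all files carry the unit
system in their header comment.  Writing is bit-stable for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import RunResult
from .metrics import ElementHistory

_TENSOR_COLS = ["xx", "yy", "zz", "xy", "yz", "xz"]
_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


def _tensor_frame(times, eids, tensors, prefix):
    rows = []
    for ti, t in enumerate(times):
        for e in eids:
            row = {"time": t, "element": e}
            for col, (i, j) in zip(_TENSOR_COLS, _IDX):
                row[f"{prefix}_{col}"] = tensors[e][ti, i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def write_histories(result: RunResult, directory) -> None:
    """Write per-quantity CSVs and the JSON run manifest.

    Error-terminated runs still get their partial histories written; the
    manifest records the termination status.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    units = result.manifest.get("units", "si")
    header = f"# units: {units}\n"

    times = result.times
    hists = result.element_histories
    eids = list(range(len(hists)))
    stress = {h.eid: h.stress for h in hists}
    strain = {h.eid: h.strain for h in hists}

    def dump(df: pd.DataFrame, name: str) -> None:
        path = directory / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    if hists:
        dump(_tensor_frame(times, eids, stress, "s"), "stress.csv")
        dump(_tensor_frame(times, eids, strain, "e"), "strain.csv")
        vol_rows = []
        for ti, t in enumerate(times):
            for h in hists:
                vol_rows.append({"time": t, "element": h.eid,
                                 "volume": h.volume_series[ti]})
        dump(pd.DataFrame(vol_rows), "volume.csv")
        dump(
            pd.DataFrame(
                [{"element": h.eid, "part": h.part, "tissue": h.tissue,
                  "side": h.side, "ref_volume": h.volume} for h in hists]
            ),
            "elements.csv",
        )

    if len(times):
        nd = result.node_displacements
        rows = []
        for ti, t in enumerate(times):
            for n in range(nd.shape[1]):
                rows.append({"time": t, "node": n, "ux": nd[ti, n, 0],
                             "uy": nd[ti, n, 1], "uz": nd[ti, n, 2]})
        dump(pd.DataFrame(rows), "nodes.csv")

        cf = result.contact_force
        dump(
            pd.DataFrame({
                "time": times, "fx": cf[:, 0], "fy": cf[:, 1], "fz": cf[:, 2],
                "magnitude": np.linalg.norm(cf, axis=1),
            }),
            "contact.csv",
        )
        dump(pd.DataFrame({"time": times, **result.energy}), "energy.csv")

    with open(directory / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_histories(directory) -> tuple[list[ElementHistory], dict]:
    """Rebuild element histories (and the manifest) from a history directory."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    meta = _read_csv(directory / "elements.csv").set_index("element")
    stress_df = _read_csv(directory / "stress.csv")
    strain_df = _read_csv(directory / "strain.csv")
    out = []
    for eid, m in meta.iterrows():
        s = stress_df[stress_df.element == eid].sort_values("time")
        e = strain_df[strain_df.element == eid].sort_values("time")
        times = s["time"].to_numpy()
        out.append(
            ElementHistory(
                eid=int(eid), part=int(m["part"]), tissue=str(m["tissue"]),
                side=str(m["side"]), volume=float(m["ref_volume"]),
                times=times,
                stress=_unpack(s, "s"),
                strain=_unpack(e, "e"),
            )
        )
    return out, manifest


def read_contact(directory) -> pd.DataFrame:
    return _read_csv(Path(directory) / "contact.csv")


def _unpack(df: pd.DataFrame, prefix: str) -> np.ndarray:
    n = len(df)
    t = np.zeros((n, 3, 3))
    for col, (i, j) in zip(_TENSOR_COLS, _IDX):
        v = df[f"{prefix}_{col}"].to_numpy()
        t[:, i, j] = v
        t[:, j, i] = v
    return t
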