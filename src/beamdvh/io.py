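"""Reading and writing DVH set files (CSV and JSON schemas).

CSV schema: one row per (patient, structure, source, grid index) with columns
``patient_id, structure_id, source, field_index, dv, bin_index, dose_gy,
total_volume_cc`` — field_index 1..9 for beams, 0 for plan/predicted curves,
bin_index 1-based over the volume grid.

JSON schema::

    {"patients": [{"patient_id": ..., "structures": [
        {"structure_id": ..., "dv": ..., "total_volume_cc": ...,
         "plan": [doses...], "predicted": [doses...]?,
         "beams": {"1": [doses...], ..., "9": [...]}}]}]}

Both round-trip losslessly for valid curves; curves are validated on read and
schema violations name the file, the offending group and the failed
invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dvh import BeamDVHSet, DVHCurve, N_BEAMS

__all__ = [
    "DVHRecord",
    "read_dvh_set",
    "write_dvh_set",
    "records_from_samples",
    "samples_from_records",
    "beam_sets_from_records",
]

CSV_COLUMNS = [
    "patient_id",
    "structure_id",
    "source",
    "field_index",
    "dv",
    "bin_index",
    "dose_gy",
    "total_volume_cc",
]


@dataclass(frozen=True)
class DVHRecord:
    patient_id: str
    structure_id: str
    source: str
    field_index: int  # 1..9 for beams, 0 otherwise
    curve: DVHCurve


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    if path.suffix == ".json":
        return "json"
    return "csv"


def write_dvh_set(records: Sequence[DVHRecord], path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frames = []
        for rec in records:
            c = rec.curve
            n = c.n_bins
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": rec.patient_id,
                        "structure_id": rec.structure_id,
                        "source": rec.source,
                        "field_index": rec.field_index,
                        "dv": c.dv,
                        "bin_index": np.arange(1, n + 1),
                        "dose_gy": c.doses,
                        "total_volume_cc": c.total_volume_cc,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        patients: Dict[str, Dict[str, dict]] = {}
        for rec in records:
            struct = patients.setdefault(rec.patient_id, {}).setdefault(
                rec.structure_id,
                {"structure_id": rec.structure_id, "dv": rec.curve.dv,
                 "total_volume_cc": rec.curve.total_volume_cc, "beams": {}},
            )
            if rec.source == "beam":
                struct["beams"][str(rec.field_index)] = rec.curve.doses.tolist()
            else:
                struct[rec.source] = rec.curve.doses.tolist()
        payload = {
            "patients": [
                {"patient_id": pid, "structures": list(structs.values())}
                for pid, structs in sorted(patients.items())
            ]
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _make_curve(path, pid, sid, source, doses, dv, vol) -> DVHCurve:
    try:
        return DVHCurve(
            structure_id=sid,
            doses=np.asarray(doses, dtype=float),
            dv=float(dv),
            total_volume_cc=None if vol is None or pd.isna(vol) else float(vol),
            source=source,
        )
    except ValueError as e:
        raise ValueError(
            f"{path}: patient {pid!r} structure {sid!r} source {source!r}: {e}"
        ) from e


def read_dvh_set(path, format: Optional[str] = None) -> List[DVHRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    records: List[DVHRecord] = []
    if fmt == "csv":
        df = pd.read_csv(path, comment="#")
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        keys = ["patient_id", "structure_id", "source", "field_index"]
        for (pid, sid, source, fi), grp in df.groupby(keys, sort=True):
            grp = grp.sort_values("bin_index")
            dv = float(grp["dv"].iloc[0])
            n_expected = round(1.0 / dv)
            bins = grp["bin_index"].to_numpy()
            if len(bins) != n_expected or not np.array_equal(
                bins, np.arange(1, n_expected + 1)
            ):
                raise ValueError(
                    f"{path}: patient {pid!r} structure {sid!r} source {source!r}: "
                    f"expected bin_index 1..{n_expected} for dv={dv}, got "
                    f"{len(bins)} rows"
                )
            vol = grp["total_volume_cc"].iloc[0]
            curve = _make_curve(path, pid, sid, source, grp["dose_gy"].to_numpy(), dv, vol)
            records.append(
                DVHRecord(str(pid), str(sid), str(source), int(fi), curve)
            )
    elif fmt == "json":
        payload = json.loads(path.read_text())
        for pat in payload.get("patients", []):
            pid = pat["patient_id"]
            for struct in pat["structures"]:
                sid = struct["structure_id"]
                dv = struct["dv"]
                vol = struct.get("total_volume_cc")
                for source in ("plan", "predicted"):
                    if source in struct:
                        curve = _make_curve(path, pid, sid, source, struct[source], dv, vol)
                        records.append(DVHRecord(pid, sid, source, 0, curve))
                for fi_str, doses in sorted(
                    struct.get("beams", {}).items(), key=lambda kv: int(kv[0])
                ):
                    curve = _make_curve(path, pid, sid, "beam", doses, dv, vol)
                    records.append(DVHRecord(pid, sid, "beam", int(fi_str), curve))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return records


def records_from_samples(
    samples: Sequence[Tuple[BeamDVHSet, Optional[DVHCurve]]]
) -> List[DVHRecord]:
    """Flatten (beam set, plan curve) samples into file records."""
    records: List[DVHRecord] = []
    for beam_set, plan in samples:
        for i, beam in enumerate(beam_set.beams):
            records.append(
                DVHRecord(beam_set.patient_id, beam_set.structure_id, "beam", i + 1, beam)
            )
        if plan is not None:
            records.append(
                DVHRecord(beam_set.patient_id, beam_set.structure_id, plan.source, 0, plan)
            )
    return records


def beam_sets_from_records(records: Sequence[DVHRecord]) -> List[BeamDVHSet]:
    """Group beam records into BeamDVHSets (ordered by field index)."""
    groups: Dict[Tuple[str, str], Dict[int, DVHCurve]] = {}
    for rec in records:
        if rec.source == "beam":
            groups.setdefault((rec.patient_id, rec.structure_id), {})[
                rec.field_index
            ] = rec.curve
    beam_sets = []
    for (pid, sid), beams in sorted(groups.items()):
        if set(beams) != set(range(1, N_BEAMS + 1)):
            raise ValueError(
                f"patient {pid!r} structure {sid!r}: expected field indices "
                f"1..{N_BEAMS}, found {sorted(beams)}"
            )
        beam_sets.append(
            BeamDVHSet(
                patient_id=pid,
                structure_id=sid,
                beams=tuple(beams[i] for i in range(1, N_BEAMS + 1)),
            )
        )
    return beam_sets


def samples_from_records(
    records: Sequence[DVHRecord], target_source: str = "plan"
) -> List[Tuple[BeamDVHSet, DVHCurve]]:
    """Pair each beam set with its composite curve of the requested source."""
    targets = {
        (r.patient_id, r.structure_id): r.curve
        for r in records
        if r.source == target_source
    }
    samples = []
    for beam_set in beam_sets_from_records(records):
        key = (beam_set.patient_id, beam_set.structure_id)
        if key not in targets:
            raise ValueError(f"no {target_source!r} curve for {key}")
        samples.append((beam_set, targets[key]))
    return samples
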