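"""Real-data ingestion: EDF/BDF recordings plus a subject table.

The real-data path expects a directory of EDF or BDF files named
``<subject_id>_<condition>.edf`` (condition in {sea, altitude}) and a
``subjects.csv`` with columns subject_id, age_years, condition.  Reading
uses MNE (an optional dependency); recordings should already be
artifact-cleaned, as this package performs no ICA or visual rejection.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .channels import region_of
from .preprocess import CONDITIONS, Recording


def read_edf(
    path: str | Path,
    subject_id: str = "",
    condition: str = "",
    region_map: dict[str, str] | None = None,
) -> Recording:
    """Load one EDF/BDF file as a :class:`Recording` (data in µV)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF/BDF requires mne; install hypoxeeg[edf]"
        ) from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    raw.pick("eeg")
    labels = list(raw.ch_names)
    if region_map is None:
        try:
            region_map = {lab: region_of(lab) for lab in labels}
        except KeyError as exc:
            raise ValueError(
                "channel labels do not follow 10-20 naming; pass region_map"
            ) from exc
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        region_map=region_map,
        subject_id=subject_id,
        condition=condition,
    )


def read_edf_study(in_dir: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    """Load a full paired study from EDF/BDF files plus subjects.csv."""
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.csv")
    recordings = []
    for _, row in table.iterrows():
        if row.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {row.condition!r}")
        candidates = [
            src / f"{row.subject_id}_{row.condition}{ext}" for ext in (".edf", ".bdf")
        ]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no EDF/BDF for {row.subject_id}/{row.condition}")
        recordings.append(
            read_edf(path, subject_id=str(row.subject_id), condition=str(row.condition))
        )
    return recordings, table
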