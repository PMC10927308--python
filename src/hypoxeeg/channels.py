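"""Standard 64-channel montage labels and the default scalp-region partition.

The montage follows the extended 10-20 naming used by 64-channel Biosemi
caps. Five scalp regions (frontal, frontocentral, centroparietal,
occipitoparietal, temporal) partition all 64 sensors; the partition is a
documented convention of this package — published head-map statistics
rarely list exact channel membership — and every entry point that consumes
a region map accepts a user override.
"""

from __future__ import annotations

# Biosemi 64-channel cap, 10-20 extended names (A1-A32 then B1-B32 positions).
BIOSEMI64_LABELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

REGIONS: tuple[str, ...] = (
    "frontal",
    "frontocentral",
    "centroparietal",
    "occipitoparietal",
    "temporal",
)

# Prefix rules, longest prefix wins: FT/TP/T -> temporal, Fp/AF/F -> frontal,
# FC/C -> frontocentral, CP/P -> centroparietal, PO/O/I -> occipitoparietal.
_PREFIX_REGION = (
    ("FT", "temporal"),
    ("TP", "temporal"),
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("FC", "frontocentral"),
    ("CP", "centroparietal"),
    ("PO", "occipitoparietal"),
    ("T", "temporal"),
    ("F", "frontal"),
    ("C", "frontocentral"),
    ("P", "centroparietal"),
    ("O", "occipitoparietal"),
    ("I", "occipitoparietal"),
)


def region_of(label: str) -> str:
    """Map a 10-20 channel label to its scalp region."""
    for prefix, region in _PREFIX_REGION:
        if label.startswith(prefix):
            return region
    raise KeyError(f"no region rule for channel label {label!r}")


def default_region_map(labels=BIOSEMI64_LABELS) -> dict[str, str]:
    """Return the default ``{channel label: region}`` partition."""
    return {lab: region_of(lab) for lab in labels}
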