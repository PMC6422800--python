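"""Default 64-channel montage (10-20 derived electrode labels).

The order is fixed: regional results ("hub at O1", "degree boost at C3")
are addressed by label, and deterministic tie-breaks throughout the
package resolve to the lowest montage index.
"""

MONTAGE_64: tuple[str, ...] = (
    # 1-10
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    # 11-20
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "IO",
    # 21-30
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "FT9", "FT10",
    # 31-40
    "TP9", "TP10", "F1", "F2", "C1", "C2", "P1", "P2", "AF3", "AF4",
    # 41-50
    "FC3", "FC4", "CP3", "CP4", "PO3", "PO4", "F5", "F6", "C5", "C6",
    # 51-60
    "P5", "P6", "AF7", "AF8", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
    # 61-64
    "FPz", "CPz", "POz", "Oz",
)


def channel_index(label: str, labels: tuple[str, ...] | list[str] = MONTAGE_64) -> int:
    """Montage index of a channel label (raises ValueError if absent)."""
    try:
        return list(labels).index(label)
    except ValueError as exc:
        raise ValueError(f"channel {label!r} not in montage") from exc
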