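"""Stimulus protocol description: block-design vibrotactile stimulation.

The experiments use 8-Hz innocuous vibrotactile stimulation of a single
distal digit pad in a block design: 30 s of stimulation followed by 30 s of
rest constitutes one epoch.  fMRI runs use 7 epochs, electrophysiology runs
use 10.  Onset times are derived from the epoch timing plus a lead-in rest
period before the first onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class StimulusProtocol:
    freq_hz: float = 8.0
    on_s: float = 30.0
    off_s: float = 30.0
    n_epochs: int = 7
    lead_in_s: float = 30.0
    digit_label: str = "right-D3"
    onsets_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.onsets_s:
            period = self.on_s + self.off_s
            self.onsets_s = [self.lead_in_s + k * period for k in range(self.n_epochs)]
        if any(b <= a for a, b in zip(self.onsets_s, self.onsets_s[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def duration_s(self) -> float:
        """Time from run start to the end of the last epoch's off period."""
        return self.onsets_s[-1] + self.on_s + self.off_s

    @property
    def side(self) -> str:
        """'left' or 'right' parsed from the digit label."""
        return "left" if self.digit_label.lower().startswith("l") else "right"

    def on_windows(self) -> list[tuple[float, float]]:
        return [(t, t + self.on_s) for t in self.onsets_s]

    def off_windows(self) -> list[tuple[float, float]]:
        return [(t + self.on_s, t + self.on_s + self.off_s) for t in self.onsets_s]

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        lines = [
            f"freq_hz={self.freq_hz}",
            f"on_s={self.on_s}",
            f"off_s={self.off_s}",
            f"n_epochs={self.n_epochs}",
            f"lead_in_s={self.lead_in_s}",
            f"digit_label={self.digit_label}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "StimulusProtocol":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        return cls(
            freq_hz=float(kv.get("freq_hz", 8.0)),
            on_s=float(kv.get("on_s", 30.0)),
            off_s=float(kv.get("off_s", 30.0)),
            n_epochs=int(kv.get("n_epochs", 7)),
            lead_in_s=float(kv.get("lead_in_s", 30.0)),
            digit_label=kv.get("digit_label", "right-D3"),
        )


def fmri_protocol(**kw) -> StimulusProtocol:
    """Default 7-epoch fMRI stimulation protocol."""
    kw.setdefault("n_epochs", 7)
    return StimulusProtocol(**kw)


def ephys_protocol(**kw) -> StimulusProtocol:
    """Default 10-epoch electrophysiology stimulation protocol."""
    kw.setdefault("n_epochs", 10)
    return StimulusProtocol(**kw)
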