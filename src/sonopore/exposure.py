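"""Dosimetry and timing arithmetic for one sonoporation treatment session.

Pulsed 1 MHz ultrasound is delivered in short bursts: 30 cycles every
625 us gives a 4.8% duty cycle at a 1.6 kHz pulse repetition frequency.
Six sites on the cell-culture chamber are treated either sequentially
(30 s exposure plus a 30 s operator switch per site, after a 1 min thermal
equalization: 7 min total in the bath) or concurrently (all six at once:
1.5 min). Microbubble dosing follows the contrast-agent arithmetic: 33 uL
of agent at 1.2e10 bubbles/mL into 10 mL of media over 6e5 seeded cells is
a 0.33% volume concentration and a 660:1 bubble-to-cell ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ExposureProtocol",
    "UcaDose",
    "duty_cycle",
    "pulse_repetition_frequency",
    "microbubble_cell_ratio",
    "uca_volume_concentration",
    "submersion_time",
    "sound_speed_relative_change",
]


@dataclass(frozen=True)
class ExposureProtocol:
    """Timing and pressure parameters of one treatment session."""

    frequency_hz: float = 1.0e6
    peak_negative_pressure_mpa: float = 0.7
    cycles_per_burst: int = 30
    burst_period_us: float = 625.0
    exposure_duration_s: float = 30.0
    switch_interval_s: float = 30.0
    equalization_time_s: float = 60.0
    n_sites: int = 6
    scheme: str = "sequential"

    def __post_init__(self) -> None:
        for name in (
            "frequency_hz",
            "burst_period_us",
            "exposure_duration_s",
            "switch_interval_s",
            "equalization_time_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cycles_per_burst <= 0:
            raise ValueError("cycles_per_burst must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.scheme not in ("sequential", "concurrent"):
            raise ValueError("scheme must be 'sequential' or 'concurrent'")
        if self.burst_duration_s > self.burst_period_us * 1e-6:
            raise ValueError("burst does not fit within the burst period")

    @property
    def burst_duration_s(self) -> float:
        return self.cycles_per_burst / self.frequency_hz


@dataclass(frozen=True)
class UcaDose:
    """Ultrasound-contrast-agent dose added to one culture chamber."""

    stock_concentration_per_ml: float = 1.2e10
    added_volume_ul: float = 33.0
    media_volume_ml: float = 10.0
    cells_seeded: float = 6.0e5

    def __post_init__(self) -> None:
        if self.stock_concentration_per_ml <= 0:
            raise ValueError("stock_concentration_per_ml must be positive")
        if self.added_volume_ul < 0:
            raise ValueError("added_volume_ul must be nonnegative")
        if self.media_volume_ml <= 0:
            raise ValueError("media_volume_ml must be positive")
        if self.cells_seeded <= 0:
            raise ValueError("cells_seeded must be positive")


def duty_cycle(protocol: ExposureProtocol) -> float:
    """Percentage of time ultrasound is on: 100 * burst duration / period."""
    return 100.0 * protocol.burst_duration_s / (protocol.burst_period_us * 1e-6)


def pulse_repetition_frequency(protocol: ExposureProtocol) -> float:
    """Burst emission rate in Hz, the reciprocal of the burst period."""
    return 1.0 / (protocol.burst_period_us * 1e-6)


def microbubble_cell_ratio(dose: UcaDose) -> float:
    """Microbubbles added per seeded cell."""
    bubbles = dose.stock_concentration_per_ml * (dose.added_volume_ul * 1e-3)
    return bubbles / dose.cells_seeded


def uca_volume_concentration(dose: UcaDose) -> float:
    """Volume concentration in percent.

    The denominator is the stated media volume (not media plus agent),
    matching the conventional 33 uL / 10 mL = 0.33% report.
    """
    return 100.0 * (dose.added_volume_ul * 1e-3) / dose.media_volume_ml


def submersion_time(protocol: ExposureProtocol) -> float:
    """Total bath time of one culture chamber, in minutes.

    Sequential scheme: equalization + n_sites * (exposure + operator switch),
    the switch interval counted after every site including the last.
    Concurrent scheme: equalization + one exposure.
    """
    if protocol.scheme == "sequential":
        total_s = protocol.equalization_time_s + protocol.n_sites * (
            protocol.exposure_duration_s + protocol.switch_interval_s
        )
    else:
        total_s = protocol.equalization_time_s + protocol.exposure_duration_s
    return total_s / 60.0


def sound_speed_relative_change(c_low_m_s: float, c_high_m_s: float) -> float:
    """Relative change in sound speed, percent of the lower value.

    E.g. warming the bath from 37 to 42 degC moves c from 1524 to 1532 m/s,
    an approximately 0.52% change.
    """
    if c_low_m_s <= 0:
        raise ValueError("sound speeds must be positive")
    return 100.0 * (c_high_m_s - c_low_m_s) / c_low_m_s


def dose_report(protocol: ExposureProtocol, dose: UcaDose) -> dict:
    """All derived exposure quantities as one JSON-serializable dict."""
    return {
        "duty_cycle_percent": duty_cycle(protocol),
        "pulse_repetition_frequency_hz": pulse_repetition_frequency(protocol),
        "burst_duration_us": protocol.burst_duration_s * 1e6,
        "microbubble_cell_ratio": microbubble_cell_ratio(dose),
        "uca_volume_concentration_percent": uca_volume_concentration(dose),
        "submersion_time_min": submersion_time(protocol),
        "scheme": protocol.scheme,
    }
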