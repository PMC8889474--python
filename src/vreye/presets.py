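"""Reference values from the paradigm's pilot sample (N=31 NTP users).

The pilot analyses reported paired t statistics with varying degrees of
freedom (pairwise deletion across metrics), Cohen's d_z effect sizes with
95% CIs, and condition means/SDs.  Those printed statistics are inputs here:
the contrast table below feeds effect-size reproduction checks, and the
condition means parameterize the session simulator's default presets.

The raw pilot data were never released; participant-level quantities derived
from them (craving means, pupil means, the r = 0.33 use-episode correlation)
are therefore generator targets, not reproducible values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PilotContrast:
    """One printed paired contrast: t, df, and the published d_z and CI."""

    key: str
    label: str
    t: float
    df: int
    d_printed: float
    ci_printed: tuple[float, float]

    @property
    def n(self) -> int:
        return self.df + 1


#: The ten printed paired contrasts of the pilot analyses.
PILOT_CONTRASTS: tuple[PilotContrast, ...] = (
    PilotContrast("craving", "craving: Active vs Neutral scenes",
                  4.24, 30, 0.76, (0.36, 1.16)),
    PilotContrast("fixation_pooled", "fixation: Active vs Neutral cues (pooled)",
                  -4.76, 30, -0.85, (-1.26, -0.44)),
    PilotContrast("fixation_patio", "fixation: Active vs Neutral cues (Patio)",
                  5.05, 29, 0.92, (0.49, 1.35)),
    PilotContrast("fixation_bbq", "fixation: Active vs Neutral cues (OutdoorBBQ)",
                  2.24, 29, 0.41, (0.03, 0.78)),
    PilotContrast("fixation_driving", "fixation: Active vs Neutral cues (Driving)",
                  -5.83, 30, -1.05, (-1.48, -0.60)),
    PilotContrast("pupil_pooled", "pupil: Active vs Neutral cues (pooled)",
                  -2.01, 28, -0.37, (-0.75, 0.01)),
    PilotContrast("pupil_patio", "pupil: Active vs Neutral cues (Patio)",
                  3.95, 27, 0.75, (0.32, 1.16)),
    PilotContrast("pupil_bbq", "pupil: Active vs Neutral cues (OutdoorBBQ)",
                  1.60, 27, 0.30, (-0.08, 0.68)),
    PilotContrast("pupil_driving", "pupil: Active vs Neutral cues (Driving)",
                  -2.07, 28, -0.38, (-0.76, -0.003)),
    PilotContrast("ebr", "EBR: Active vs Neutral scenes",
                  0.49, 30, 0.09, (-0.26, 0.44)),
)

#: Contrasts whose printed CI matches the rounded-d normal-approximation
#: reconstruction exactly at two decimals; the remainder agree within 0.01
#: per bound (published rounding artifacts).
CI_EXACT_KEYS = frozenset({"craving", "fixation_pooled", "fixation_patio", "ebr"})

#: Pilot condition and sample summaries used as simulator presets.
PILOT_MEANS = {
    "craving_active_mean": 42.77,
    "craving_active_sd": 34.07,
    "craving_neutral_mean": 29.42,
    "craving_neutral_sd": 25.54,
    "pupil_active_mean_mm": 3.87,
    "pupil_active_sd_mm": 0.78,
    "pupil_neutral_mean_mm": 3.97,
    "pupil_neutral_sd_mm": 0.71,
    "ipq_total": 60.05,
    "ipq_total_sd": 9.66,
    "vrsq_total": 16.25,
    "vrsq_total_sd": 13.94,
    "use_episodes_90d_mean": 772.29,
    "use_episodes_90d_sd": 1008.20,
    "bias_use_episodes_r": 0.33,
}

#: Spontaneous blink-rate plausibility band (blinks per minute): the majority
#: of pilot participants fell within it.
EBR_BAND_PER_MIN = (12.0, 40.0)
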