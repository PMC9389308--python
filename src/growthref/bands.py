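"""Centile-band classification of standard deviation scores.

Two schemes are used in dual-chart screening practice:

* a five-band scheme with cutoffs at SDS −1.88, −1.66, +1.66, +1.88
  (nominally the 3rd, 10th, 90th and 97th centiles) carrying per-measure
  clinical labels (underweight/overweight/obesity for weight and BMI,
  growth deficiency/high growth for height);
* a three-band scheme — under (< 3rd centile), norm (3rd–97th), over
  (> 97th) — used for the headline chart comparison.

The five-band cutoffs are the conventional printed SDS values; note that
SDS ±1.66 is *not* the exact normal quantile of the 10th/90th centile
(±1.2816).  The scheme is applied as conventionally printed; pass
``exact_quantiles=True`` for the normal-quantile variant in sensitivity
analyses.

Boundary inclusivity: z = −1.88 falls in the 3rd–10th band (normal, and
"norm" in the three-band scheme); z = +1.88 falls in the 90th–97th band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lms import centile_to_z

__all__ = [
    "BandScheme",
    "FIVE_BAND",
    "THREE_BAND",
    "five_band_scheme",
    "three_band_scheme",
    "classify_five",
    "classify_three",
    "THREE_BAND_ORDER",
]

THREE_BAND_ORDER = ("under", "norm", "over")

#: five-band labels per measure, in band order (lowest z first)
_FIVE_LABELS = {
    "weight": ("Underweight", "Normal", "Normal", "Overweight", "Obesity"),
    "height": ("Growth deficiency", "Normal", "Normal", "Normal", "High growth"),
    "bmi": ("Underweight", "Normal", "Normal", "Overweight", "Obesity"),
}


@dataclass(frozen=True)
class BandScheme:
    """An exhaustive, mutually exclusive partition of the SDS axis.

    ``cutoffs`` are the k−1 interior thresholds of k bands, strictly
    increasing.  ``upper_inclusive[i]`` says whether z == cutoffs[i] belongs
    to the band below (True) or above (False).  ``labels`` maps a measure to
    the k band labels, lowest band first.
    """

    name: str
    cutoffs: tuple[float, ...]
    upper_inclusive: tuple[bool, ...]
    labels: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if len(self.upper_inclusive) != len(self.cutoffs):
            raise ValueError("one inclusivity flag per cutoff required")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        k = len(self.cutoffs) + 1
        for measure, labs in self.labels.items():
            if len(labs) != k:
                raise ValueError(f"{measure}: need {k} labels, got {len(labs)}")

    def band_index(self, z):
        """0-based band index for ``z`` (scalar or array)."""
        z = np.asarray(z, dtype=float)
        if np.any(~np.isfinite(z)):
            raise ValueError("z must be finite")
        idx = np.zeros(z.shape, dtype=int)
        for cut, inclusive in zip(self.cutoffs, self.upper_inclusive):
            above = (z > cut) if inclusive else (z >= cut)
            idx += above.astype(int)
        return idx if idx.ndim else int(idx)

    def classify(self, z, measure: str):
        """Band label(s) for ``z`` under this scheme's ``measure`` labels."""
        try:
            labs = self.labels[measure]
        except KeyError:
            raise ValueError(f"unknown measure {measure!r}") from None
        idx = self.band_index(z)
        if np.ndim(idx) == 0:
            return labs[idx]
        return np.asarray(labs, dtype=object)[idx]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoffs": list(self.cutoffs),
            "upper_inclusive": list(self.upper_inclusive),
            "labels": {m: list(v) for m, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandScheme":
        return cls(name=d["name"], cutoffs=tuple(d["cutoffs"]),
                   upper_inclusive=tuple(d["upper_inclusive"]),
                   labels={m: tuple(v) for m, v in d["labels"].items()})


def five_band_scheme(exact_quantiles: bool = False) -> BandScheme:
    """The five-band scheme (3rd/10th/90th/97th centile cutoffs).

    With ``exact_quantiles`` the cutoffs are the normal quantiles of those
    centiles instead of the conventional SDS values ±1.88 / ±1.66.
    """
    if exact_quantiles:
        cuts = tuple(centile_to_z(p) for p in (3, 10, 90, 97))
    else:
        cuts = (-1.88, -1.66, 1.66, 1.88)
    # z == -1.88 belongs to the band above (>=), z == 1.66 to the band
    # below (<=): flags read "cutoff belongs to the lower band".
    return BandScheme(name="five_band", cutoffs=cuts,
                      upper_inclusive=(False, False, True, True),
                      labels=dict(_FIVE_LABELS))


def three_band_scheme(exact_quantiles: bool = False) -> BandScheme:
    """The three-band screening scheme: under / norm / over (3rd, 97th)."""
    if exact_quantiles:
        cuts = (centile_to_z(3), centile_to_z(97))
    else:
        cuts = (-1.88, 1.88)
    labels = {m: THREE_BAND_ORDER for m in _FIVE_LABELS}
    return BandScheme(name="three_band", cutoffs=cuts,
                      upper_inclusive=(False, True), labels=labels)


FIVE_BAND = five_band_scheme()
THREE_BAND = three_band_scheme()


def classify_five(z, measure: str, scheme: BandScheme | None = None):
    """Five-band clinical label for SDS ``z`` and ``measure``."""
    return (scheme or FIVE_BAND).classify(z, measure)


def classify_three(z, scheme: BandScheme | None = None):
    """Three-band label for SDS ``z``: under / norm / over."""
    return (scheme or THREE_BAND).classify(z, "weight")
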