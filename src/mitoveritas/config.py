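"""Screening thresholds and marker definitions.

All numeric decision thresholds used by the symptom detectors live here so a
screen is fully described by one :class:`ScreenConfig`.  Defaults separate the
two divergence scales the method assumes: intraspecific variation of roughly
a percent or less, and interspecific divergence upwards of several percent.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

#: Canonical (full-gene) marker lengths in bp for the three protein-coding
#: mitochondrial markers used for authentication, and the minimum fragment
#: length at which a marker is considered usable evidence.  The usable floor
#: is strict: a COI fragment of exactly 600 bp is not usable.
MARKER_CANONICAL_LENGTH = {"COI": 696, "CYTB": 1143, "ND2": 1041}
MARKER_MIN_USABLE_LENGTH = {"COI": 600, "CYTB": 800, "ND2": 800}
MARKER_NAMES = ("COI", "CYTB", "ND2")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the authentication screen.

    Attributes
    ----------
    min_len, max_len : int
        Candidate length window in bp; sequences outside it are not screened.
        Both bounds inclusive.
    min_identity : float
        Minimum alignment identity for a marker locator hit to count.  Set
        well below one minus the largest heterospecific divergence the screen
        must tolerate, so that marker copies from the wrong species are still
        located and then flagged downstream.
    tau_close : float
        p-distance at or below which a heterospecific match counts as
        "close" (symptom: close match outside the conspecific clade).
    tau_deep : float
        Nearest-conspecific p-distance above which a placement outside the
        conspecific clade counts as a deep divergence.
    tau_noid : float
        p-distance above which a sequence (or divergent region) is said to
        match *no* species in the panel.
    theta_lb : float
        Long-branch multiplier: a terminal branch longer than ``theta_lb``
        times the conspecific median terminal branch (with floor
        ``lb_floor``) fires the long-branch symptom.
    lb_floor : float
        Floor for the conspecific median terminal branch, in
        substitutions/site, preventing the long-branch rule from firing on
        noise when conspecific references are nearly identical.
    multiple_indel_min : int
        Number of independent indel events in one marker alignment required
        to fire the multiple-indels symptom ("multiple" means at least 2).
    window, step : int
        Sliding-window size and stride (bp) for chimera localization.
    min_run : int
        Window runs shorter than this are absorbed into the flanking
        assignment before segments are reported.
    dup_window, dup_max_dist, dup_min_hits : int
        Self-duplication scan: probe length, maximum edit distance for a
        probe hit elsewhere in the genome, and the number of hitting probes
        required to call a duplicated marker span.
    """

    min_len: int = 12_000
    max_len: int = 25_000
    min_identity: float = 0.60
    tau_close: float = 0.03
    tau_deep: float = 0.05
    tau_noid: float = 0.10
    theta_lb: float = 5.0
    lb_floor: float = 0.005
    multiple_indel_min: int = 2
    window: int = 150
    step: int = 50
    min_run: int = 1
    dup_window: int = 100
    dup_max_dist: int = 10
    dup_min_hits: int = 2

    def replace(self, **kwargs) -> "ScreenConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str) -> ScreenConfig:
    """Read a TOML file with a ``[screen]`` table (or flat keys) into a config."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("screen", data)
    known = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ScreenConfig(**table)


DEFAULT_CONFIG = ScreenConfig()
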