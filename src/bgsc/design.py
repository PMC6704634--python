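"""Nested knockdown designs and the reduction of regulation modes to pattern groups.

A nested RNAi design stimulates cells (e.g. with EGF) under a panel of
knockdown treatments, each silencing a subset of the candidate regulator
channels.  A *regulation mode* is one hypothesis about which channels drive a
gene: with ``k`` channels there are ``2**k`` modes.  A mode responds to the
stimulus under a given treatment iff at least one of its regulator channels
survives the knockdown.  Modes with identical response profiles across all
treatments are observationally indistinguishable; collapsing them yields the
*pattern groups* whose binary indicator vectors parameterize the per-gene
likelihood models of :mod:`bgsc.model`.

For the canonical EGFR design (channels: splice-variant-I receptor, the
truncated isoforms II–IV, other EGF receptors; treatments: no RNAi, siRNA
against variant I, siRNA against all variants) the eight modes A–H collapse
to four groups a–d, and group c — genes regulated via isoforms II–IV and not
via other receptors — is the prediction target.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "RegulatorChannel",
    "KnockdownTreatment",
    "NestedDesign",
    "RegulationMode",
    "PatternGroup",
    "DesignError",
    "EGFR_DESIGN",
    "enumerate_modes",
    "mode_response",
    "derive_pattern_groups",
    "load_design",
    "resolve_design",
]


class DesignError(ValueError):
    """Raised for structurally invalid designs or design files."""


@dataclass(frozen=True)
class RegulatorChannel:
    """One candidate regulator route from the stimulus to a gene."""

    name: str


@dataclass(frozen=True)
class KnockdownTreatment:
    """A treatment silencing a (possibly empty) set of regulator channels."""

    name: str
    knocked_down: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "knocked_down", frozenset(self.knocked_down))


@dataclass(frozen=True)
class NestedDesign:
    """An ordered panel of knockdown treatments over shared regulator channels.

    The first treatment must be the control (nothing knocked down).  Each
    treatment contributes two experimental conditions — without and with the
    stimulus — so a design with ``T`` treatments observes ``2*T`` expression
    values per gene, interleaved as (no-stimulus, stimulus) per treatment.
    """

    channels: tuple[RegulatorChannel, ...]
    treatments: tuple[KnockdownTreatment, ...]
    stimulus_name: str = "EGF"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if not self.channels:
            raise DesignError("a design needs at least one regulator channel")
        if not self.treatments:
            raise DesignError("a design needs at least one treatment")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate channel names: {names}")
        tnames = [t.name for t in self.treatments]
        if len(set(tnames)) != len(tnames):
            raise DesignError(f"duplicate treatment names: {tnames}")
        if self.treatments[0].knocked_down:
            raise DesignError(
                "the first treatment must be the control (empty knockdown), got "
                f"{sorted(self.treatments[0].knocked_down)}"
            )
        known = set(names)
        for t in self.treatments:
            unknown = t.knocked_down - known
            if unknown:
                raise DesignError(
                    f"treatment {t.name!r} knocks down unknown channels {sorted(unknown)}"
                )

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def n_conditions(self) -> int:
        return 2 * len(self.treatments)

    @property
    def condition_labels(self) -> tuple[str, ...]:
        """Labels x1..x_{2T}-style: per treatment, no-stimulus then stimulus."""
        labels = []
        for t in self.treatments:
            labels.append(f"{t.name}")
            labels.append(f"{t.name}+{self.stimulus_name}")
        return tuple(labels)


@dataclass(frozen=True)
class RegulationMode:
    """A subset of regulator channels hypothesized to drive a gene."""

    label: str
    regulators: frozenset[str]


@dataclass(frozen=True)
class PatternGroup:
    """An equivalence class of regulation modes with one observable pattern.

    ``indicator`` is the binary vector g1..g_{2T}: position ``2t`` (1-based,
    the stimulated condition of treatment ``t``) is 1 iff member modes respond
    to the stimulus under that treatment; all no-stimulus positions are 0.
    ``member_modes`` lists the confounded modes the group cannot distinguish.
    """

    label: str
    indicator: tuple[int, ...]
    member_modes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_null(self) -> bool:
        """True for the all-zero (stimulus-unresponsive) group."""
        return not any(self.indicator)

    @property
    def n_means(self) -> int:
        """Number of distinct condition means under this group's model."""
        return 1 if self.is_null else 2


#: The study's EGFR design: 2 EGF levels x {no RNAi, siRNA_I, siRNA_ALL}.
EGFR_DESIGN = NestedDesign(
    channels=(
        RegulatorChannel("isoform_I"),
        RegulatorChannel("isoforms_II_IV"),
        RegulatorChannel("other_receptors"),
    ),
    treatments=(
        KnockdownTreatment("control"),
        KnockdownTreatment("siRNA_I", frozenset({"isoform_I"})),
        KnockdownTreatment("siRNA_ALL", frozenset({"isoform_I", "isoforms_II_IV"})),
    ),
    stimulus_name="EGF",
)

# Published letter layout for three-channel designs, as index subsets into the
# design's channel order (0 = first channel). Reproduces A..H of the EGFR study.
_THREE_CHANNEL_LETTER_ORDER: tuple[tuple[int, ...], ...] = (
    (),        # A: no regulator
    (2,),      # B: third channel only (other receptors)
    (1,),      # C: second channel only (isoforms II-IV)
    (0,),      # D: first channel only (isoform I)
    (1, 2),    # E
    (0, 1, 2), # F
    (0, 2),    # G
    (0, 1),    # H
)


def _letter_labels(n: int, alphabet: str) -> list[str]:
    """A, B, ..., Z, AA, AB, ... (or lowercase) — n labels."""
    labels: list[str] = []
    for i in range(n):
        s, j = "", i
        while True:
            s = alphabet[j % 26] + s
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(s)
    return labels


def enumerate_modes(design: NestedDesign) -> list[RegulationMode]:
    """All ``2**k`` regulation modes of a design, deterministically labeled.

    Three-channel designs use the published A–H letter layout; other channel
    counts order subsets by size, then by channel position, and letter them
    in that order.
    """
    k = len(design.channels)
    names = design.channel_names
    if k == 3:
        subsets: Iterable[tuple[int, ...]] = _THREE_CHANNEL_LETTER_ORDER
    else:
        subsets = sorted(
            (
                combo
                for r in range(k + 1)
                for combo in itertools.combinations(range(k), r)
            ),
            key=lambda c: (len(c), c),
        )
    labels = _letter_labels(2**k, string.ascii_uppercase)
    return [
        RegulationMode(label, frozenset(names[i] for i in subset))
        for label, subset in zip(labels, subsets)
    ]


def mode_response(
    mode: RegulationMode, treatment: KnockdownTreatment, design: NestedDesign
) -> int:
    """1 iff the mode still has a live regulator channel under the treatment.

    A gene driven by ``mode`` shows stimulus-responsive expression under a
    treatment exactly when at least one of its regulator channels is not
    knocked down by that treatment.
    """
    surviving = set(design.channel_names) - treatment.knocked_down
    return int(bool(mode.regulators & surviving))


def derive_pattern_groups(design: NestedDesign) -> list[PatternGroup]:
    """Collapse regulation modes into observably distinct pattern groups.

    Each mode's per-treatment response vector is spread onto the ``2*T``
    interleaved conditions (no-stimulus positions fixed at 0); modes sharing
    an indicator vector are merged.  Groups are labeled a, b, c, ... with the
    all-zero group first, then by decreasing number of responsive conditions,
    ties broken by earlier responsive treatments first.
    """
    modes = enumerate_modes(design)
    by_indicator: dict[tuple[int, ...], list[str]] = {}
    for mode in modes:
        indicator = []
        for t in design.treatments:
            indicator.append(0)
            indicator.append(mode_response(mode, t, design))
        by_indicator.setdefault(tuple(indicator), []).append(mode.label)

    def sort_key(item: tuple[tuple[int, ...], list[str]]):
        indicator, _ = item
        ones = sum(indicator)
        # all-zero first; then more responsive treatments first; then the
        # pattern whose 1s sit at earlier treatments first.
        return (ones != 0, -ones, tuple(-g for g in indicator))

    ordered = sorted(by_indicator.items(), key=sort_key)
    labels = _letter_labels(len(ordered), string.ascii_lowercase)
    return [
        PatternGroup(label, indicator, tuple(sorted(members)))
        for label, (indicator, members) in zip(labels, ordered)
    ]


# ---------------------------------------------------------------------------
# design files


def _design_from_dict(doc: Mapping) -> NestedDesign:
    try:
        channels = tuple(RegulatorChannel(str(c)) for c in doc["channels"])
        treatments = tuple(
            KnockdownTreatment(
                str(t["name"]), frozenset(str(c) for c in t.get("knocked_down", []))
            )
            for t in doc["treatments"]
        )
    except (KeyError, TypeError) as exc:
        raise DesignError(f"malformed design description: {exc!r}") from exc
    return NestedDesign(channels, treatments, str(doc.get("stimulus", "EGF")))


def load_design(path: str) -> NestedDesign:
    """Read a design from a YAML file (channels / treatments / stimulus keys)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise DesignError(f"design file {path} does not contain a mapping")
    return _design_from_dict(doc)


def resolve_design(spec: str) -> NestedDesign:
    """Map the literal ``"egfr-default"`` to the built-in design, else load a file."""
    if spec == "egfr-default":
        return EGFR_DESIGN
    return load_design(spec)
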