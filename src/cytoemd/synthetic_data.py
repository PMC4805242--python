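"""Synthetic flow-cytometry-like data generators.

Real basophil-activation data have a dominant resting population and a
smaller activated subset shifted along one or more marker channels, with
run-to-run instrument drift adding small translations that carry no
biology.  The generators here emulate exactly that structure with Gaussian
mixtures, in transformed-intensity units (unit-SD populations):

* :func:`sample_mixture` — events from an explicit Gaussian mixture;
* :func:`shift_series` — a reference N(0,1) population versus mixtures
  whose minor component walks away in fixed SD increments (the classic
  demonstration that a transport distance keeps growing where p-value
  statistics plateau);
* :func:`gen_cohort` — paired control/stimulated samples for two subject
  classes: responders up-regulate a subpopulation across two marker
  channels (with imperfect coordination between the markers), some
  non-responders show nonspecific single-channel elevation, and every
  stimulated sample carries a small nuisance drift.

All generators are seed-deterministic: the same arguments produce
byte-identical event matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .flow_io import EventMatrix

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "Subject",
    "sample_mixture",
    "shift_series",
    "gen_cohort",
]


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian component: mean vector, per-channel SD vector, weight."""

    mean: tuple[float, ...]
    sd: tuple[float, ...]
    weight: float

    def __post_init__(self) -> None:
        mean = tuple(float(v) for v in np.atleast_1d(self.mean))
        sd = tuple(float(v) for v in np.atleast_1d(self.sd))
        if len(sd) == 1 and len(mean) > 1:
            sd = sd * len(mean)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if len(sd) != len(mean):
            raise ParameterError("mean and sd dimensionality differ")
        if any(s <= 0 for s in sd):
            raise ParameterError(f"component SDs must be positive, got {sd}")
        if not 0.0 <= self.weight <= 1.0:
            raise ParameterError(f"component weight {self.weight} outside [0, 1]")


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture to draw N events from, with a mandatory seed."""

    components: tuple[MixtureComponent, ...]
    n_events: int
    seed: int
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ParameterError("mixture needs at least one component")
        if self.n_events < 1:
            raise ParameterError(f"n_events must be >= 1, got {self.n_events}")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"component weights sum to {total}, expected 1")
        dims = {len(c.mean) for c in comps}
        if len(dims) != 1:
            raise ParameterError("all components must share dimensionality")
        d = dims.pop()
        channels = self.channels or tuple(f"ch{i + 1}" for i in range(d))
        if len(channels) != d:
            raise ParameterError(f"{len(channels)} channel names for {d} dimensions")
        object.__setattr__(self, "channels", tuple(channels))


def sample_mixture(spec: MixtureSpec) -> EventMatrix:
    """Draw N events; component counts are multinomial in the weights, and
    rows are shuffled so event order carries no component information."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    counts = rng.multinomial(spec.n_events, weights)
    d = len(spec.components[0].mean)
    blocks = []
    for component, count in zip(spec.components, counts):
        if count == 0:
            continue
        mean = np.asarray(component.mean)
        sd = np.asarray(component.sd)
        blocks.append(rng.normal(mean, sd, size=(count, d)))
    values = np.concatenate(blocks, axis=0)
    values = values[rng.permutation(values.shape[0])]
    return EventMatrix(values, spec.channels)


def shift_series(
    shifts: Sequence[float],
    minor_fraction: float = 0.2,
    n_events: int = 20_000,
    seed: int = 0,
    channel: str = "signal",
) -> list[tuple[EventMatrix, EventMatrix]]:
    """Reference N(0,1) versus (1-pi) N(0,1) + pi N(s,1) for each shift s.

    Emulates a moving-subpopulation experiment: a single reference draw, and
    a single mixture draw whose minor component is *translated* by each s in
    turn (the same cells walking away, as when increasing doses of a drug
    push one subset's marker expression up).  Because every series element
    shares the same underlying events, differences along the series reflect
    the separation itself rather than re-sampling noise.
    """
    if any(s < 0 for s in shifts):
        raise ParameterError(f"shifts must be non-negative, got {list(shifts)}")
    if not 0.0 < minor_fraction < 1.0:
        raise ParameterError(f"minor_fraction must be in (0, 1), got {minor_fraction}")
    ref_seq, base_seq = np.random.SeedSequence(seed).spawn(2)
    reference = sample_mixture(
        MixtureSpec(
            (MixtureComponent((0.0,), (1.0,), 1.0),),
            n_events,
            int(ref_seq.generate_state(1)[0] % 2**31),
            (channel,),
        )
    )
    rng = np.random.default_rng(base_seq)
    n_minor = rng.multinomial(n_events, [1.0 - minor_fraction, minor_fraction])[1]
    base = rng.standard_normal(n_events)
    order = rng.permutation(n_events)  # fixed interleaving of main/minor
    minor_mask = np.zeros(n_events, dtype=bool)
    minor_mask[:n_minor] = True
    base, minor_mask = base[order], minor_mask[order]
    pairs = []
    for s in shifts:
        values = base + float(s) * minor_mask
        pairs.append((reference, EventMatrix(values[:, None], (channel,))))
    return pairs


@dataclass(frozen=True)
class Subject:
    """One subject's paired samples with the ground-truth class label."""

    subject_id: str
    label: str  # "responder" | "nonresponder"
    control: EventMatrix
    stimulated: EventMatrix


def gen_cohort(
    n_per_class: int,
    effect: float,
    nuisance_drift: float = 0.0,
    n_events: int = 5_000,
    seed: int = 0,
    responding_fraction: float = 0.2,
    coordinated_fraction: float = 0.5,
    nonspecific_scale: float = 0.5,
    channels: tuple[str, str] = ("CD203c", "CD63"),
) -> list[Subject]:
    """Paired control/stimulated cohorts with two responder classes.

    Controls are N(0, I) on two marker channels; stimulated samples of
    *every* subject are translated by the nuisance drift (magnitude
    ``nuisance_drift``, split across both channels, so a non-responder's
    control-to-stimulated EMD is ~ the drift magnitude).

    Responders up-regulate a ``responding_fraction`` subpopulation, but the
    response is *poorly coordinated* across the two markers, as activated
    basophils are: every responder shifts the first channel by ``effect``,
    while only a ``coordinated_fraction`` of them (assigned
    deterministically by subject index) also shifts the second channel, by
    ``nonspecific_scale * effect``.  Half the non-responders show
    *nonspecific* second-channel elevation of the same subpopulation at
    exactly that same magnitude.  Consequences: the second channel's
    marginal distribution is class-exchangeable by construction — half of
    each class elevated by the identical amount — so a single-channel MFI
    delta on it carries no class information at all, while the two-channel
    EMD still orders the classes cleanly (at least responding_fraction *
    effect for every responder versus at most responding_fraction *
    nonspecific_scale * effect plus drift for every non-responder).  With
    ``effect=0`` every shift vanishes and the classes are exchangeable.
    """
    if n_per_class < 1:
        raise ParameterError(f"n_per_class must be >= 1, got {n_per_class}")
    if effect < 0 or nuisance_drift < 0:
        raise ParameterError("effect and nuisance_drift must be non-negative")
    if not 0.0 < responding_fraction < 1.0:
        raise ParameterError(
            f"responding_fraction must be in (0, 1), got {responding_fraction}"
        )
    if not 0.0 <= coordinated_fraction <= 1.0 or not 0.0 <= nonspecific_scale <= 1.0:
        raise ParameterError(
            "coordinated_fraction and nonspecific_scale must lie in [0, 1]"
        )
    drift_per_channel = nuisance_drift / np.sqrt(2.0)
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    n_coordinated = int(round(coordinated_fraction * n_per_class))
    subjects: list[Subject] = []
    for i in range(2 * n_per_class):
        responder = i < n_per_class
        within = i if responder else i - n_per_class
        label = "responder" if responder else "nonresponder"
        sub_seeds = children[i].spawn(2)
        ctrl_seed = int(sub_seeds[0].generate_state(1)[0] % 2**31)
        stim_seed = int(sub_seeds[1].generate_state(1)[0] % 2**31)
        control = sample_mixture(
            MixtureSpec(
                (MixtureComponent((0.0, 0.0), (1.0, 1.0), 1.0),),
                n_events,
                ctrl_seed,
                channels,
            )
        )
        base_mean = (drift_per_channel, drift_per_channel)
        second_channel = nonspecific_scale * effect
        if responder:
            # first channel always responds; second only for the
            # "coordinated" responders (first n_coordinated by index),
            # and by the same amount as nonspecific elevation so the
            # second channel's marginal is class-exchangeable
            shift = (
                effect,
                second_channel if within < n_coordinated else 0.0,
            )
        else:
            # nonspecific single-channel elevation for half the controls
            shift = (
                0.0,
                second_channel if within < n_per_class // 2 else 0.0,
            )
        if effect > 0 and any(s != 0.0 for s in shift):
            comps = (
                MixtureComponent(base_mean, (1.0, 1.0), 1.0 - responding_fraction),
                MixtureComponent(
                    (base_mean[0] + shift[0], base_mean[1] + shift[1]),
                    (1.0, 1.0),
                    responding_fraction,
                ),
            )
        else:
            comps = (MixtureComponent(base_mean, (1.0, 1.0), 1.0),)
        stimulated = sample_mixture(MixtureSpec(comps, n_events, stim_seed, channels))
        subjects.append(Subject(f"subj{i + 1:02d}", label, control, stimulated))
    return subjects
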