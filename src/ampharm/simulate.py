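"""Synthetic plate-level concentration-response data.

Generates raw agonist concentration-response panels with the statistical
structure the analysis pipeline assumes: log-spaced concentrations,
3-parameter logistic true curves (optionally with non-unity Hill slopes),
technical replicates, independent experiments with between-experiment potency
jitter, additive Gaussian noise, and WT/mutant pairing within each experiment
at both receptors.

Key modelling choices (see docs/methods.md for rationale):

* response units are arbitrary; the WT span is 100 units on a basal of 0;
* noise is additive Gaussian with SD = ``noise_sd_frac`` x WT span;
* between-experiment variability has two components, calibrated so that
  simulated summary SEs reproduce the printed SE magnitudes: a Gaussian
  jitter on pEC50 shared by the WT and mutant curves of the same experiment
  (paired design), and an independent multiplicative jitter on each curve's
  span (transfection/cell-density variation), which is what gives Emax (%WT)
  its realistic between-experiment spread;
* every random stream is derived deterministically from the master seed and
  a stable hash of (construct, receptor, experiment index), so generation is
  a pure function of the configuration.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnknownConstructError
from .fitting import logistic4

__all__ = [
    "ConstructSpec",
    "SyntheticPanelConfig",
    "DoseResponseExperiment",
    "default_concentrations",
    "generate_panel",
    "table2_scenario",
    "write_panel_csv",
    "read_panel_csv",
]

RECEPTORS = ("AM1", "AM2")

#: plateau (as % of WT span) used to emulate "no curve" mutants
DEAD_CURVE_EMAX_PCT = 2.0
DEAD_CURVE_PEC50 = 7.0

RAW_CSV_COLUMNS = ["construct", "receptor", "experiment", "conc_molar", "replicate", "response"]


def default_concentrations() -> tuple[float, ...]:
    """Thirteen half-log agonist concentrations from 1e-12 to 1e-6 M.

    Centred on the WT potency of the AM receptors (pEC50 ~ 9, i.e. EC50
    1 nM) with 3 log units on either side, so that the plateau of strongly
    potency-shifted mutants (pEC50 ~ 7) is still defined by the top
    concentrations.
    """
    return tuple(10.0 ** (-12.0 + 0.5 * k) for k in range(13))


@dataclass(frozen=True)
class ConstructSpec:
    """True generating parameters for one construct at one receptor.

    ``wt_partner`` names the WT construct paired with a mutant within each
    experiment; it is None for WT constructs themselves.  ``true_emax_pct_wt``
    is the plateau expressed as percent of the WT span (WT = 100).
    """

    construct: str
    receptor: str
    true_pec50: float
    true_emax_pct_wt: float = 100.0
    true_basal: float = 0.0
    true_hill: float = 1.0
    wt_partner: str | None = None
    n_experiments: int | None = None  # overrides the panel-wide count
    #: extra per-experiment pEC50 scatter of this curve, on top of the shared
    #: (paired) jitter; lets heterogeneous published SEs be emulated per row
    pec50_extra_sd: float = 0.0
    #: per-curve relative span jitter; None falls back to the panel default
    span_sd_frac: float | None = None


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Generating configuration for a synthetic panel (the "stated world")."""

    constructs: tuple[ConstructSpec, ...]
    n_experiments: int = 5
    n_tech_replicates: int = 3
    concentrations: tuple[float, ...] = field(default_factory=default_concentrations)
    noise_sd_frac: float = 0.10
    between_experiment_sd: float = 0.20
    between_experiment_span_sd: float = 0.20
    wt_span: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) == 0 or np.any(conc <= 0):
            raise ConfigurationError("concentrations: must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ConfigurationError("concentrations: must be strictly increasing")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments: must be >= 1")
        if self.n_tech_replicates < 1:
            raise ConfigurationError("n_tech_replicates: must be >= 1")
        if self.noise_sd_frac < 0:
            raise ConfigurationError("noise_sd_frac: must be >= 0")
        if self.between_experiment_sd < 0:
            raise ConfigurationError("between_experiment_sd: must be >= 0")
        if self.between_experiment_span_sd < 0:
            raise ConfigurationError("between_experiment_span_sd: must be >= 0")
        ids = {(c.construct, c.receptor) for c in self.constructs}
        for c in self.constructs:
            if c.receptor not in RECEPTORS:
                raise ConfigurationError(
                    f"constructs: receptor {c.receptor!r} not one of {RECEPTORS}"
                )
            if c.wt_partner is not None and (c.wt_partner, c.receptor) not in ids:
                raise ConfigurationError(
                    f"constructs: mutant {c.construct!r} has no WT partner "
                    f"{c.wt_partner!r} at receptor {c.receptor}"
                )


@dataclass(frozen=True)
class DoseResponseExperiment:
    """One experiment's raw replicates for one construct at one receptor.

    ``points`` is a tuple of (concentration_molar, responses) pairs.  The WT
    curve measured in the same experiment shares the ``experiment`` id; for a
    mutant record ``wt_construct`` names it, for a WT record it is None.
    """

    construct: str
    receptor: str
    experiment: str
    points: tuple[tuple[float, tuple[float, ...]], ...]
    wt_construct: str | None = None

    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.points)


def _stream(seed: int, construct: str, receptor: str, exp_index: int, tag: int):
    """Deterministic per-(construct, receptor, experiment) random stream."""
    key = zlib.crc32(f"{construct}|{receptor}".encode("utf-8"))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key, exp_index, tag))
    return np.random.default_rng(ss)


def _simulate_curve(
    spec: ConstructSpec,
    config: SyntheticPanelConfig,
    pec50: float,
    rng,
) -> tuple[tuple[float, tuple[float, ...]], ...]:
    logc = np.log10(np.asarray(config.concentrations, dtype=float))
    span = config.wt_span * spec.true_emax_pct_wt / 100.0
    span_sd = (
        spec.span_sd_frac
        if spec.span_sd_frac is not None
        else config.between_experiment_span_sd
    )
    if span_sd > 0:
        # per-curve expression/response-scale variation; truncated at 10 %
        # of nominal so a live curve never degenerates to a dead one
        factor = 1.0 + span_sd * rng.standard_normal()
        span *= max(factor, 0.1)
    if spec.pec50_extra_sd > 0:
        pec50 = pec50 + spec.pec50_extra_sd * rng.standard_normal()
    mean = logistic4(logc, spec.true_basal, spec.true_basal + span, pec50, spec.true_hill)
    sd = config.noise_sd_frac * config.wt_span
    points = []
    for c, mu in zip(config.concentrations, mean):
        if sd > 0:
            reps = mu + sd * rng.standard_normal(config.n_tech_replicates)
        else:
            reps = np.full(config.n_tech_replicates, mu)
        points.append((float(c), tuple(float(r) for r in reps)))
    return tuple(points)


def generate_panel(config: SyntheticPanelConfig) -> list[DoseResponseExperiment]:
    """Generate the raw experiments of a synthetic panel.

    For every mutant construct and experiment index, a paired WT curve is
    generated under the same experiment id and the same pEC50 jitter draw;
    WT-only constructs (no mutant referencing them) are generated standalone.
    Bit-identical output is guaranteed for identical (config, seed).
    """
    config.validate()
    by_key = {(c.construct, c.receptor): c for c in config.constructs}
    referenced_wt = {
        (c.wt_partner, c.receptor) for c in config.constructs if c.wt_partner is not None
    }
    out: list[DoseResponseExperiment] = []
    for spec in config.constructs:
        if spec.wt_partner is None and (spec.construct, spec.receptor) in referenced_wt:
            continue  # generated alongside each referencing mutant
        n_exp = spec.n_experiments or config.n_experiments
        for k in range(n_exp):
            exp_id = f"{spec.construct}.{k + 1}"
            jitter_rng = _stream(config.seed, spec.construct, spec.receptor, k, tag=0)
            jitter = (
                config.between_experiment_sd * jitter_rng.standard_normal()
                if config.between_experiment_sd > 0
                else 0.0
            )
            if spec.wt_partner is not None:
                wt = by_key[(spec.wt_partner, spec.receptor)]
                wt_rng = _stream(config.seed, spec.construct, spec.receptor, k, tag=1)
                out.append(
                    DoseResponseExperiment(
                        construct=wt.construct,
                        receptor=wt.receptor,
                        experiment=exp_id,
                        points=_simulate_curve(wt, config, wt.true_pec50 + jitter, wt_rng),
                    )
                )
            mut_rng = _stream(config.seed, spec.construct, spec.receptor, k, tag=2)
            out.append(
                DoseResponseExperiment(
                    construct=spec.construct,
                    receptor=spec.receptor,
                    experiment=exp_id,
                    points=_simulate_curve(spec, config, spec.true_pec50 + jitter, mut_rng),
                    wt_construct=spec.wt_partner,
                )
            )
    return out


def table2_scenario(
    receptor: str,
    mutant_ids: Sequence[str],
    n_experiments: int | None = None,
    seed: int = 0,
    emulate_dispersion: bool = True,
    **overrides,
) -> SyntheticPanelConfig:
    """Generating config whose true parameters equal the packaged cAMP table.

    Each requested mutant gets true pEC50 and Emax (%WT) equal to the printed
    means, with a paired WT construct taken from the WT column of the same
    row; "no curve" mutants are emulated as near-flat responders (2 % of the
    WT span).  The per-construct experiment count follows the printed n
    unless ``n_experiments`` forces a common count.  With an empty selection
    the config contains a single WT whose pEC50 is the mean of the WT column.

    The published SEs are strongly heterogeneous across rows, and the
    inferential layer is sensitive to exactly that structure, so each curve
    also receives the per-experiment dispersion its printed SEs imply: extra
    pEC50 scatter sqrt(max(se^2 * n - shared_jitter^2, 0)) beyond the shared
    between-experiment jitter, and a relative span jitter of
    emax_se * sqrt(n) / emax for the mutant curve (capped at 75 %).  Pass
    ``emulate_dispersion=False`` for an idealized world controlled purely by
    the panel-wide noise knobs (e.g. the zero-noise recovery checks).
    """
    from .fixtures import load_table2

    if receptor not in RECEPTORS:
        raise ConfigurationError(f"receptor: {receptor!r} not one of {RECEPTORS}")
    table = load_table2()
    table = table[table["receptor"] == receptor].set_index("construct")
    unknown = [m for m in mutant_ids if m not in table.index]
    if unknown:
        raise UnknownConstructError(
            f"unknown mutant ids {unknown}; valid ids: {sorted(table.index)}"
        )
    defaults = SyntheticPanelConfig(constructs=())
    shared_sd = float(overrides.get("between_experiment_sd", defaults.between_experiment_sd))

    def extra_sd(se: float, n: int) -> float:
        if not emulate_dispersion:
            return 0.0
        return math.sqrt(max(se * se * n - shared_sd * shared_sd, 0.0))

    constructs: list[ConstructSpec] = []
    if not mutant_ids:
        constructs.append(
            ConstructSpec(
                construct="WT",
                receptor=receptor,
                true_pec50=float(table["wt_pec50"].mean()),
            )
        )
    for m in mutant_ids:
        row = table.loc[m]
        wt_id = f"WT[{m}]"
        n_row = int(n_experiments or row["n"])
        constructs.append(
            ConstructSpec(
                construct=wt_id,
                receptor=receptor,
                true_pec50=float(row["wt_pec50"]),
                pec50_extra_sd=extra_sd(float(row["wt_se"]), n_row),
                span_sd_frac=0.05 if emulate_dispersion else None,
            )
        )
        if bool(row["censored"]):
            mut = ConstructSpec(
                construct=m,
                receptor=receptor,
                true_pec50=DEAD_CURVE_PEC50,
                true_emax_pct_wt=DEAD_CURVE_EMAX_PCT,
                wt_partner=wt_id,
                n_experiments=n_row,
            )
        else:
            emax = float(row["emax_pct"])
            mut = ConstructSpec(
                construct=m,
                receptor=receptor,
                true_pec50=float(row["mut_pec50"]),
                true_emax_pct_wt=emax,
                wt_partner=wt_id,
                n_experiments=n_row,
                pec50_extra_sd=extra_sd(float(row["mut_se"]), n_row),
                span_sd_frac=(
                    min(float(row["emax_se"]) * math.sqrt(n_row) / emax, 0.75)
                    if emulate_dispersion
                    else None
                ),
            )
        constructs.append(mut)
    return SyntheticPanelConfig(constructs=tuple(constructs), seed=seed, **overrides)


def write_panel_csv(exps: Iterable[DoseResponseExperiment], path: str | Path) -> None:
    """Write raw experiments in the plate CSV dialect.

    Columns ``construct,receptor,experiment,conc_molar,replicate,response``;
    UTF-8, '.' decimal, header row mandatory.  Full float precision (repr);
    rounding is confined to the display renderer.
    """
    rows = []
    for e in exps:
        for conc, responses in e.points:
            for i, r in enumerate(responses, start=1):
                rows.append((e.construct, e.receptor, e.experiment, conc, i, r))
    df = pd.DataFrame(rows, columns=RAW_CSV_COLUMNS)
    # %.17g guarantees bit-exact float round-trip through the text file
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_panel_csv(path: str | Path) -> list[DoseResponseExperiment]:
    """Read the plate CSV dialect back into experiments.

    WT/mutant pairing is reconstructed from the shared experiment id: a
    mutant record is paired with the WT construct observed under the same
    (receptor, experiment).  WT constructs are recognised by an id starting
    with "WT".
    """
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in RAW_CSV_COLUMNS if c not in df.columns]
    if missing:
        from .errors import InputError

        raise InputError(f"raw CSV missing columns {missing}")
    out = []
    wt_by_exp: dict[tuple[str, str], str] = {}
    for (construct, receptor, experiment), g in df.groupby(
        ["construct", "receptor", "experiment"], sort=False
    ):
        if str(construct).startswith("WT"):
            wt_by_exp[(receptor, experiment)] = construct
    for (construct, receptor, experiment), g in df.groupby(
        ["construct", "receptor", "experiment"], sort=False
    ):
        points = tuple(
            (float(conc), tuple(float(r) for r in cg["response"]))
            for conc, cg in g.groupby("conc_molar", sort=True)
        )
        wt = wt_by_exp.get((receptor, experiment))
        out.append(
            DoseResponseExperiment(
                construct=str(construct),
                receptor=str(receptor),
                experiment=str(experiment),
                points=points,
                wt_construct=None if str(construct).startswith("WT") else wt,
            )
        )
    return out
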