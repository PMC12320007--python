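"""Synthetic cohorts with known ground truth.

Emulates the study conditions end-to-end: a pseudo-randomised block design
(six conditions, 15.75 s stimulus blocks each followed by a 7.875 s
baseline), six-region BOLD series at TR = 1.45 s generated from a known
"true" model, plus i.i.d. Gaussian observation noise.  Every random choice
derives from a master seed through per-subject seed sequences, so cohorts
regenerate bit-identically and each manifest suffices to re-simulate its
clean series exactly.

Ground-truth parameters combine a fixed physiological template (forward
V1 coupling 0.3 Hz, intrahemispheric OFA/FFA coupling 0.1-0.2 Hz, weak
homotopic baseline coupling 0.05 Hz, driving gains 0.8 Hz), small
per-subject jitter, and "planted" modulatory effects — named B entries
with fixed magnitude and sign (defaults 0.3-0.45 Hz) that downstream
recovery analyses can score against.  Draws are rejected until the
effective coupling matrix (at rest and during each single face condition)
is strictly stable.

Two problem-size profiles ship as configs: a reduced profile (2 blocks
per condition, 200 scans) used throughout the test suite, and the
full-session profile (8 blocks per condition, 795 scans).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .generative_model import (
    HemodynamicParameters,
    NeuralParameters,
    SimulationOutput,
    add_noise,
    integrate,
)
from .network_model import (
    MODULATORY_INPUTS,
    N_REGIONS,
    REGIONS,
    ModelSpec,
    get_model,
    region_index,
)
from .paradigm import RegressorSet, build_regressors, generate_schedule

__all__ = [
    "GroupConfig",
    "SamplingRule",
    "SubjectDataset",
    "DEFAULT_PLANTED",
    "sample_parameters",
    "generate_subject",
    "generate_group",
]


def _default_planted() -> dict[str, float]:
    """Default planted modulatory effects, keyed ``"MOD:src->tgt"``.

    Central faces modulate every inter-regional edge; peripheral faces
    modulate only edges whose source carries activity in those blocks
    (the undriven V1 stays near rest, so its outgoing modulations would
    be unidentifiable).  The pattern follows the qualitative physiology:
    transfer away from the stimulated hemisphere is excitatory, the
    return direction inhibitory for peripheral stimulation, and roughly
    symmetric for central stimulation.
    """
    planted: dict[str, float] = {}

    def put(mod: str, src: str, tgt: str, value: float) -> None:
        planted[f"{mod}:{src}->{tgt}"] = value

    # central: near-symmetric homotopic transfer, forward facilitation
    put("CF", "lFFA", "rFFA", 0.40)
    put("CF", "rFFA", "lFFA", 0.35)
    put("CF", "lOFA", "rOFA", 0.30)
    put("CF", "rOFA", "lOFA", -0.30)
    for src, tgt in (
        ("lOFA", "lFFA"), ("rOFA", "rFFA"),
        ("lFFA", "lOFA"), ("rFFA", "rOFA"),
        ("lV1", "lOFA"), ("rV1", "rOFA"),
        ("lV1", "lFFA"), ("rV1", "rFFA"),
    ):
        put("CF", src, tgt, 0.35)

    # left hemifield -> right V1 driven: strong R->L transfer, inhibited return
    put("LF", "rOFA", "lOFA", 0.45)
    put("LF", "lOFA", "rOFA", -0.35)
    put("LF", "rFFA", "lFFA", 0.45)
    put("LF", "lFFA", "rFFA", -0.35)
    for src, tgt in (
        ("rV1", "rOFA"), ("rV1", "rFFA"),
        ("rOFA", "rFFA"), ("rFFA", "rOFA"),
        ("lOFA", "lFFA"), ("lFFA", "lOFA"),
    ):
        put("LF", src, tgt, 0.30)

    # right hemifield: mirror image
    put("RF", "lOFA", "rOFA", 0.45)
    put("RF", "rOFA", "lOFA", -0.35)
    put("RF", "lFFA", "rFFA", 0.45)
    put("RF", "rFFA", "lFFA", -0.35)
    for src, tgt in (
        ("lV1", "lOFA"), ("lV1", "lFFA"),
        ("lOFA", "lFFA"), ("lFFA", "lOFA"),
        ("rOFA", "rFFA"), ("rFFA", "rOFA"),
    ):
        put("RF", src, tgt, 0.30)
    return planted


DEFAULT_PLANTED: dict[str, float] = _default_planted()

# endogenous template (Hz): (source, target) -> value
_A_TEMPLATE = {
    ("lV1", "lOFA"): 0.3, ("rV1", "rOFA"): 0.3,
    ("lV1", "lFFA"): 0.3, ("rV1", "rFFA"): 0.3,
    ("lOFA", "lFFA"): 0.2, ("rOFA", "rFFA"): 0.2,
    ("lFFA", "lOFA"): 0.1, ("rFFA", "rOFA"): 0.1,
    ("lOFA", "rOFA"): 0.05, ("rOFA", "lOFA"): 0.05,
    ("lFFA", "rFFA"): 0.05, ("rFFA", "lFFA"): 0.05,
}
# self log-scalings: positive values = faster decay, larger for V1
_SELF_TEMPLATE = {"V1": 0.8, "OFA": 0.5, "FFA": 0.5}
_C_TEMPLATE_VALUE = 0.4

#: required stability margin (max real eigenvalue) for accepted draws
_STABILITY_MARGIN = -0.15


@dataclass
class SamplingRule:
    """Per-subject jitter around the parameter template (SDs in Hz;
    the self-scaling jitter is unitless)."""

    a_jitter_sd: float = 0.10
    self_jitter_sd: float = 0.10
    c_jitter_sd: float = 0.20
    b_jitter_sd: float = 0.0
    max_rejections: int = 1000


@dataclass
class GroupConfig:
    """Specification of one synthetic cohort."""

    n_subjects: int
    true_models: list[str]
    blocks_per_condition: int = 2
    n_scans: int = 200
    tr: float = 1.45
    bins_per_scan: int = 16
    target_snr: float = 1.0
    noise_sd: float | None = None
    planted: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLANTED))
    rule: SamplingRule = field(default_factory=SamplingRule)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.true_models, str):
            self.true_models = [self.true_models] * self.n_subjects
        if len(self.true_models) != self.n_subjects:
            raise ValueError("true_models must have one entry per subject")
        if self.noise_sd is None and self.target_snr <= 0:
            raise ValueError("noise level must be positive")
        if isinstance(self.rule, dict):
            self.rule = SamplingRule(**self.rule)

    @classmethod
    def reduced(cls, n_subjects: int, true_models, master_seed: int = 0,
                **kw) -> "GroupConfig":
        """Reduced-scale profile: 2 blocks/condition, 200 scans."""
        return cls(n_subjects=n_subjects, true_models=true_models,
                   blocks_per_condition=2, n_scans=200,
                   master_seed=master_seed, **kw)

    @classmethod
    def full_session(cls, n_subjects: int, true_models, master_seed: int = 0,
                     **kw) -> "GroupConfig":
        """Full-session profile: 8 blocks/condition, 795 analysed scans."""
        return cls(n_subjects=n_subjects, true_models=true_models,
                   blocks_per_condition=8, n_scans=795,
                   master_seed=master_seed, **kw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class SubjectDataset:
    """One synthetic subject: noisy series plus full ground truth."""

    subject_id: str
    bold: SimulationOutput
    clean: SimulationOutput
    regressors: RegressorSet
    true_model: str
    true_params: NeuralParameters
    seeds: dict[str, int]
    noise_meta: dict

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.bold.to_tsv(d / "bold.tsv")
        self.regressors.to_tsv(d / "design.tsv")
        truth = {
            "subject_id": self.subject_id,
            "true_model": self.true_model,
            "tr": self.bold.tr,
            "seeds": self.seeds,
            "noise": self.noise_meta,
            "A": self.true_params.a.tolist(),
            "B": {name: self.true_params.b[k].tolist()
                  for k, name in enumerate(MODULATORY_INPUTS)},
            "C": self.true_params.c.tolist(),
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))


def _parse_planted_key(key: str) -> tuple[str, int, int]:
    """``"CF:lFFA->rFFA"`` -> (modulator, target index, source index)."""
    mod, _, edge = key.partition(":")
    src, _, tgt = edge.partition("->")
    if mod not in MODULATORY_INPUTS or not src or not tgt:
        raise ValueError(f"malformed planted-effect key {key!r}")
    return mod, region_index(tgt.strip()), region_index(src.strip())


def _is_stable(params: NeuralParameters) -> bool:
    """Strict stability of the effective coupling at rest and during any
    single face condition."""
    a_eff = params.a_eff()
    mats = [a_eff] + [a_eff + params.b[k] for k in range(len(MODULATORY_INPUTS))]
    return all(
        np.max(np.linalg.eigvals(m).real) < _STABILITY_MARGIN for m in mats
    )


def sample_parameters(
    spec: ModelSpec,
    rule: SamplingRule | None = None,
    seed: int | np.random.Generator = 0,
    planted: dict[str, float] | None = None,
) -> NeuralParameters:
    """Draw mask-compliant ground-truth parameters.

    Template values plus Gaussian jitter per the rule; planted effects
    override the drawn B entries wherever the model's mask admits them
    (planted edges outside the mask are ignored, so one planted table can
    serve every true model in a mixed cohort).  Draws are rejected until
    the dynamics are strictly stable.
    """
    rule = rule or SamplingRule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted = DEFAULT_PLANTED if planted is None else planted
    s = spec.structure

    for _ in range(rule.max_rejections):
        params = NeuralParameters.zeros()
        for (src, tgt), val in _A_TEMPLATE.items():
            i, j = region_index(tgt), region_index(src)
            if s.a_mask[i, j]:
                params.a[i, j] = val + rule.a_jitter_sd * rng.standard_normal()
        for r, label in enumerate(REGIONS):
            base = _SELF_TEMPLATE[label[1:]]
            params.a[r, r] = base + rule.self_jitter_sd * rng.standard_normal()
        for i in range(N_REGIONS):
            for k in range(s.c_mask.shape[1]):
                if s.c_mask[i, k]:
                    params.c[i, k] = (
                        _C_TEMPLATE_VALUE + rule.c_jitter_sd * rng.standard_normal()
                    )
        if rule.b_jitter_sd > 0:
            for m, name in enumerate(MODULATORY_INPUTS):
                mask = s.b_masks[name]
                params.b[m][mask] = rule.b_jitter_sd * rng.standard_normal(
                    int(mask.sum())
                )
        for key, val in planted.items():
            mod, i, j = _parse_planted_key(key)
            m = MODULATORY_INPUTS.index(mod)
            if s.b_masks[mod][i, j]:
                params.b[m, i, j] = val
        if _is_stable(params):
            return params
    raise RuntimeError(
        f"no stable parameter draw for {spec.id} after "
        f"{rule.max_rejections} rejections; template or jitter too aggressive"
    )


def _subject_seeds(master_seed: int, index: int) -> dict[str, int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    vals = np.random.default_rng(ss).integers(0, 2**31 - 1, size=3)
    return {
        "schedule": int(vals[0]),
        "parameters": int(vals[1]),
        "noise": int(vals[2]),
    }


def generate_subject(config: GroupConfig, index: int) -> SubjectDataset:
    """Simulate one subject of the cohort (deterministic in the config)."""
    if not (0 <= index < config.n_subjects):
        raise IndexError("subject index out of range")
    seeds = _subject_seeds(config.master_seed, index)
    spec = get_model(config.true_models[index])
    schedule = generate_schedule(config.blocks_per_condition, seed=seeds["schedule"])
    regressors = build_regressors(
        schedule, tr=config.tr, bins_per_scan=config.bins_per_scan,
        n_scans=config.n_scans,
    )
    params = sample_parameters(
        spec, rule=config.rule, seed=seeds["parameters"], planted=config.planted
    )
    clean = integrate(spec, params, regressors=regressors, n_scans=config.n_scans)
    if config.noise_sd is not None:
        noisy, meta = add_noise(clean, noise_sd=config.noise_sd,
                                seed=seeds["noise"])
    else:
        noisy, meta = add_noise(clean, target_snr=config.target_snr,
                                seed=seeds["noise"])
    return SubjectDataset(
        subject_id=f"sub-{index:02d}",
        bold=noisy,
        clean=clean,
        regressors=regressors,
        true_model=spec.id,
        true_params=params,
        seeds=seeds,
        noise_meta=meta,
    )


def generate_group(
    config: GroupConfig, directory: str | Path | None = None
) -> tuple[list[SubjectDataset], dict]:
    """Simulate the whole cohort; optionally write TSV/JSON per subject.

    Returns the datasets and a manifest recording every seed, true model
    and parameter set (sufficient to re-simulate each clean series).
    """
    datasets = [generate_subject(config, i) for i in range(config.n_subjects)]
    manifest = {
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "n_scans": config.n_scans,
        "tr": config.tr,
        "blocks_per_condition": config.blocks_per_condition,
        "true_model_counts": {
            m: config.true_models.count(m) for m in sorted(set(config.true_models))
        },
        "subjects": [
            {
                "subject_id": d.subject_id,
                "true_model": d.true_model,
                "seeds": d.seeds,
                "A": d.true_params.a.tolist(),
                "B": {name: d.true_params.b[k].tolist()
                      for k, name in enumerate(MODULATORY_INPUTS)},
                "C": d.true_params.c.tolist(),
                "noise": d.noise_meta,
            }
            for d in datasets
        ],
    }
    if directory is not None:
        root = Path(directory)
        root.mkdir(parents=True, exist_ok=True)
        for d in datasets:
            d.write(root / d.subject_id)
        (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return datasets, manifest
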