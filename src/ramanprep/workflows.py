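"""End-to-end preprocessing-trial orchestration.

Builds the synthetic study: component pools from simulated source spectra,
a recombination training set with a disjoint held-out validation set,
optional trained models (on recombination and/or mathsim data), the
classical comparators, and a JSON-ready report of per-method RMSE /
L-infinity distributions, percentage reductions and paired significance
tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .baselines import polynomial_preprocess, wavelet_preprocess
from .decompose import build_component_pools
from .io import PairCollection, Spectrum, ValidationError
from .metrics import DegenerateInputError, linf, paired_test, rmse
from .model import ModelConfig, TrainedPreprocessor, train_model
from .synthesis import SynthesisConfig, build_dataset, generate_mathsim_sources

__all__ = ["TrialConfig", "run_preprocessing_trial"]

KNOWN_METHODS = ("raw", "polyfit", "wavelet", "model_mathsim", "model_recombination")


@dataclass
class TrialConfig:
    """Configuration of the experimental preprocessing trial.

    ``n_sources`` defaults to one source spectrum per ten synthesized
    pairs (the source-to-pair ratio of the training-data factory).
    """

    methods: tuple[str, ...] = ("raw", "polyfit", "wavelet", "model_recombination")
    n_train: int = 2000
    n_validation: int = 100
    n_sources: int | None = None
    severity: str = "baseline_dominated"
    grid_len: int = 1024
    seed: int = 0
    model: dict = field(default_factory=lambda: {"preset": "desk"})

    def __post_init__(self):
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}; known: {KNOWN_METHODS}")
        if self.n_train < 1 or self.n_validation < 1:
            raise ValidationError("need positive train and validation sizes")
        if self.n_sources is None:
            self.n_sources = max(10, (self.n_train + self.n_validation) // 10)


def _ids(pairs) -> set[str]:
    return {hashlib.sha1(p.x.tobytes()).hexdigest() for p in pairs}


def _apply_method(name: str, spectra: list, models: dict) -> list:
    if name == "raw":
        return spectra
    if name == "polyfit":
        return [polynomial_preprocess(s) for s in spectra]
    if name == "wavelet":
        return [wavelet_preprocess(s) for s in spectra]
    return models[name].preprocess_batch(spectra)


def run_preprocessing_trial(cfg: TrialConfig, log=None) -> dict:
    """Run the full trial and return the comparison report.

    The report holds, per method, the validation RMSE / L-infinity mean,
    SD and median; pairwise mean-reduction percentages
    ``100*(1 - mean_a/mean_b)``; two-sided Wilcoxon signed-rank p-values
    per method pair; and full provenance (seeds, sizes, severity).
    """
    say = log or (lambda *_: None)
    base = SynthesisConfig(grid_len=cfg.grid_len, seed=cfg.seed).with_severity(cfg.severity)

    say(f"building pools from {cfg.n_sources} simulated source spectra")
    src_rng = np.random.default_rng(cfg.seed + 101)
    sources = generate_mathsim_sources(cfg.n_sources, base, src_rng)
    pools = build_component_pools(sources)

    n_total = cfg.n_train + cfg.n_validation
    recomb = build_dataset(
        SynthesisConfig(**{**asdict(base), "n_spectra": n_total, "seed": cfg.seed + 202}),
        "recombination",
        pools,
    )
    train_pairs = recomb.pairs[: cfg.n_train]
    val_pairs = recomb.pairs[cfg.n_train :]
    if _ids(train_pairs) & _ids(val_pairs):
        raise ValidationError("train/validation split is not disjoint")
    train_c = PairCollection(recomb.axis, train_pairs, recomb.provenance)

    model_kwargs = dict(cfg.model)
    preset = model_kwargs.pop("preset", "desk")
    models: dict[str, TrainedPreprocessor] = {}
    if "model_recombination" in cfg.methods:
        say(f"training model on {cfg.n_train} recombination pairs")
        mcfg = ModelConfig.preset(preset, grid_len=cfg.grid_len, seed=cfg.seed + 303,
                                  **model_kwargs)
        models["model_recombination"] = train_model(train_c, mcfg, log=log)
    if "model_mathsim" in cfg.methods:
        say(f"training model on {cfg.n_train} mathsim pairs")
        msim = build_dataset(
            SynthesisConfig(**{**asdict(base), "n_spectra": cfg.n_train, "seed": cfg.seed + 404}),
            "mathsim",
        )
        mcfg = ModelConfig.preset(preset, grid_len=cfg.grid_len, seed=cfg.seed + 303,
                                  **model_kwargs)
        models["model_mathsim"] = train_model(msim, mcfg, log=log)

    axis = recomb.axis
    val_spectra = [Spectrum(axis, p.x) for p in val_pairs]
    truth = [p.y for p in val_pairs]

    per_method: dict[str, dict] = {}
    errs: dict[str, dict[str, np.ndarray]] = {}
    for name in cfg.methods:
        say(f"evaluating {name}")
        done = _apply_method(name, val_spectra, models)
        r = np.array([rmse(s.intensity, y) for s, y in zip(done, truth)])
        l = np.array([linf(s.intensity, y) for s, y in zip(done, truth)])
        errs[name] = {"rmse": r, "linf": l}
        per_method[name] = {
            m: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                "median": float(np.median(v))}
            for m, v in (("rmse", r), ("linf", l))
        }

    reductions: dict[str, dict] = {}
    pvalues: dict[str, dict] = {}
    for a in cfg.methods:
        for b in cfg.methods:
            if a == b:
                continue
            key = f"{a}_vs_{b}"
            reductions[key] = {
                m: float(100.0 * (1.0 - errs[a][m].mean() / errs[b][m].mean()))
                for m in ("rmse", "linf")
            }
            if a < b:
                pv = {}
                for m in ("rmse", "linf"):
                    try:
                        pv[m] = paired_test(errs[a][m], errs[b][m], "signed_rank")
                    except DegenerateInputError:
                        pv[m] = "identical"
                pvalues[f"{a}|{b}"] = pv

    return {
        "per_method": per_method,
        "per_spectrum": {
            name: {m: errs[name][m].tolist() for m in ("rmse", "linf")} for name in cfg.methods
        },
        "reductions_pct": reductions,
        "wilcoxon_p": pvalues,
        "provenance": {
            "config": {**asdict(cfg), "methods": list(cfg.methods)},
            "n_pools": {"noises": len(pools.noises), "baselines": len(pools.baselines),
                        "peaks": len(pools.peaks)},
            "split": {"n_train": cfg.n_train, "n_validation": cfg.n_validation,
                      "disjoint": True},
        },
    }
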