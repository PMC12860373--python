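"""Synthetic coformer libraries with known ground truth.

The experimental 159-entry suitability library behind the screen is not
public, so model and search stages are exercised on generated libraries
that emulate its shape: small hydrophilic candidate molecules (MW 75-400
g/mol, HBD 0-6, TPSA 0-150 Å², tyrosinase score in [0, 1]) labeled by a
*planted* axis-aligned decision rule, with tunable label noise and a
planted unique optimum whose descriptor profile mirrors tranexamic acid.
Because the ground truth is planted, every downstream claim (learnability,
feature ranking, optimizer recovery) can be checked against an oracle.

Synthetic records carry real small-molecule SMILES drawn from a bundled
pool so the SMILES encoder is exercised, but their tabulated descriptors
are sampled values, not recomputed from the structure: the planted rule,
not the structure, is the ground truth here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .library import CoformerLibrary, CoformerRecord

__all__ = [
    "PlantedRule",
    "GeneratorConfig",
    "GenerationError",
    "planted_rule",
    "generate_library",
    "generate_candidate_pool",
    "SMILES_POOL",
    "TRANEXAMIC_ACID_SMILES",
]

TRANEXAMIC_ACID_SMILES = "NCC1CCC(CC1)C(=O)O"

#: Real small-molecule SMILES (amino acids, organic acids, phenolics,
#: sugars, common actives) used to decorate synthetic records.
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)O", "OCC(O)CO", "OC(=O)C(O)C(O)C(=O)O", "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "NCC(=O)O", "CC(N)C(=O)O", "CC(C)CC(N)C(=O)O", "NC(CO)C(=O)O",
    "NC(CS)C(=O)O", "NC(CC(=O)O)C(=O)O", "NC(CCC(=O)O)C(=O)O", "NC(Cc1ccccc1)C(=O)O",
    "NC(Cc1ccc(O)cc1)C(=O)O", "NC(Cc1c[nH]c2ccccc12)C(=O)O", "NC(CCCCN)C(=O)O",
    "NC(CCCNC(=N)N)C(=O)O", "OC(=O)CCC(=O)O", "OC(=O)CCCCC(=O)O", "OC(=O)C=CC(=O)O",
    "OCC1OC(O)C(O)C(O)C1O", "OCC(O)C(O)C(O)C(O)CO", "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O",
    "Oc1ccccc1", "Oc1ccc(O)cc1", "Oc1ccccc1O", "Oc1cccc(O)c1",
    "Oc1ccc(cc1)C(=O)O", "OC(=O)c1ccccc1O", "OC(=O)c1ccccc1", "Nc1ccc(cc1)C(=O)O",
    "Oc1ccc(C=CC(=O)O)cc1", "COc1cc(C=CC(=O)O)ccc1O", "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O", "Oc1ccc(cc1)C1CC(=O)c2c(O)cc(O)cc2O1",
    "OCC(O)C1OC(=O)C(O)=C1O", "CN1CCCC1c1cccnc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(=O)Nc1ccc(O)cc1", "CC(=O)Oc1ccccc1C(=O)O", "OC(=O)C(O)C(O)C(=O)O",
    "NC(=O)c1ccncc1", "OC(=O)c1ccncc1", "Nc1ncnc2[nH]cnc12", "O=c1[nH]cnc2[nH]cnc12",
    "NC(CCC(N)=O)C(=O)O", "NC(CC(N)=O)C(=O)O", "OC1CCCCC1", "OC1CCC(O)CC1",
    "NCCO", "NCCCO", "OCCO", "OCCOCCO", "NCCN", "NCCS(=O)(=O)O",
    "CC(O)C(=O)O", "CCC(=O)O", "CCCC(=O)O", "CC(C)C(=O)O",
    "OCC(=O)O", "OC(CC(=O)O)C(=O)O", "NC1CCC(CC1)C(=O)O", "NCC1CCCCC1",
    "OC(=O)C1CCC(CC1)C(=O)O", "NCCc1ccc(O)c(O)c1", "NCCc1c[nH]c2ccccc12",
    "OCc1ccccc1", "OCc1ccc(O)cc1", "COc1ccc(C=O)cc1O", "Oc1ccc(C=O)cc1",
    "CC1=CC(=O)c2ccccc2C1=O", "OC(=O)CCc1ccccc1", "OC(=O)C=Cc1ccccc1",
    "NCCCC(N)C(=O)O", "NC(CCSC)C(=O)O", "CC(C)C(N)C(=O)O", "CC(CC(N)C(=O)O)C",
    "OCC1OC(O)(CO)C(O)C1O", "OC1COC(O)C(O)C1O", "NC(C(C)O)C(=O)O",
    "OC(=O)CN", "OC(=O)CCN", "OC(=O)CCCN", "OC(=O)CCCCN",
    "Oc1ccc2ccccc2c1", "Oc1ccc(Cl)cc1", "Nc1ccccc1C(=O)O", "Nc1cccc(C(=O)O)c1",
    TRANEXAMIC_ACID_SMILES,
)


class GenerationError(RuntimeError):
    """Raised when a generator target cannot be met within bounded retries."""


@dataclass(frozen=True)
class PlantedRule:
    """Axis-aligned ground-truth rule: suitable iff every threshold holds.

    Closed intervals throughout, so a record exactly on a boundary is
    suitable. The continuous score is the sum of per-descriptor signed
    margins to the nearest violated/satisfied boundary, each normalized by
    its reference span, so records deep inside the box outrank borderline
    ones and the score is comparable across descriptors.
    """

    hbd_range: tuple[int, int] = (1, 4)
    tpsa_range: tuple[float, float] = (20.0, 90.0)
    mw_cap: float = 250.0
    tyr_min: float = 0.5
    # reference spans used to normalize margins (default: sampling ranges)
    spans: dict = field(
        default_factory=lambda: {"mw": 325.0, "hbd": 6.0, "tpsa": 150.0, "tyr_inhib": 1.0}
    )

    def margins(self, mw: float, hbd: int, tpsa: float, tyr: float) -> dict[str, float]:
        return {
            "hbd": min(hbd - self.hbd_range[0], self.hbd_range[1] - hbd) / self.spans["hbd"],
            "tpsa": min(tpsa - self.tpsa_range[0], self.tpsa_range[1] - tpsa)
            / self.spans["tpsa"],
            "mw": (self.mw_cap - mw) / self.spans["mw"],
            "tyr_inhib": (tyr - self.tyr_min) / self.spans["tyr_inhib"],
        }


def planted_rule(rec: CoformerRecord, rule: PlantedRule) -> tuple[int, float]:
    """Ground-truth (label, score) for one record.

    Label is 1 iff all thresholds are satisfied (closed bounds); the score
    is the margin-weighted sum used for ranking and optimum checks.
    """
    if None in (rec.mw, rec.hbd, rec.tpsa, rec.tyr_inhib):
        raise ValueError(f"record {rec.id!r}: missing descriptors for rule evaluation")
    m = rule.margins(rec.mw, rec.hbd, rec.tpsa, rec.tyr_inhib)
    label = int(all(v >= 0 for v in m.values()))
    return label, float(sum(m.values()))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic library generation.

    Defaults mirror the screen this package emulates: n = 159 entries,
    10 % label noise, hydrophilic small-molecule descriptor ranges, and a
    planted optimum with tranexamic acid's computed descriptors
    (MW 157.21 g/mol, HBD 2, TPSA 63.32 Å²) and a high bioactivity score.
    """

    n: int = 159
    balance: float = 0.5
    noise: float = 0.1
    mw_range: tuple[float, float] = (75.0, 400.0)
    hbd_range: tuple[int, int] = (0, 6)
    tpsa_range: tuple[float, float] = (0.0, 150.0)
    tyr_range: tuple[float, float] = (0.0, 1.0)
    rule: PlantedRule = field(default_factory=PlantedRule)
    optimum_profile: dict = field(
        default_factory=lambda: {"mw": 157.21, "hbd": 2, "tpsa": 63.32, "tyr_inhib": 0.98}
    )
    optimum_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")
        if not 0.0 <= self.balance <= 1.0:
            raise ValueError("balance must lie in [0, 1]")
        for lo, hi in (self.mw_range, self.hbd_range, self.tpsa_range, self.tyr_range):
            if lo > hi:
                raise ValueError("distribution bounds invalid")


def _sample_general(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    return {
        "mw": float(rng.uniform(*cfg.mw_range)),
        "hbd": int(rng.integers(cfg.hbd_range[0], cfg.hbd_range[1] + 1)),
        "tpsa": float(rng.uniform(*cfg.tpsa_range)),
        "tyr_inhib": float(rng.uniform(*cfg.tyr_range)),
    }


def _sample_inside_rule(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    r = cfg.rule
    mw_hi = min(r.mw_cap, cfg.mw_range[1])
    h_lo, h_hi = max(r.hbd_range[0], cfg.hbd_range[0]), min(r.hbd_range[1], cfg.hbd_range[1])
    t_lo, t_hi = max(r.tpsa_range[0], cfg.tpsa_range[0]), min(r.tpsa_range[1], cfg.tpsa_range[1])
    y_lo, y_hi = max(r.tyr_min, cfg.tyr_range[0]), cfg.tyr_range[1]
    if cfg.mw_range[0] > mw_hi or h_lo > h_hi or t_lo > t_hi or y_lo > y_hi:
        raise GenerationError("class-balance target unsatisfiable: rule box is empty "
                              "within the sampling ranges")
    return {
        "mw": float(rng.uniform(cfg.mw_range[0], mw_hi)),
        "hbd": int(rng.integers(h_lo, h_hi + 1)),
        "tpsa": float(rng.uniform(t_lo, t_hi)),
        "tyr_inhib": float(rng.uniform(y_lo, y_hi)),
    }


def _make_record(rec_id: str, desc: dict, smiles: str, label: int | None) -> CoformerRecord:
    return CoformerRecord(
        id=rec_id,
        smiles=smiles,
        mw=desc["mw"],
        hbd=desc["hbd"],
        tpsa=desc["tpsa"],
        tyr_inhib=desc["tyr_inhib"],
        label=label,
        descriptor_source="supplied",
    )


def generate_library(cfg: GeneratorConfig = GeneratorConfig()) -> CoformerLibrary:
    """Generate a labeled library of ``cfg.n`` records.

    A fraction ``cfg.balance`` of records is drawn inside the planted-rule
    box (suitable before noise), the rest from the full descriptor ranges;
    labels are the rule output with each one independently flipped at the
    noise rate. Fully seeded; the generation manifest is embedded in the
    library metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[CoformerRecord] = []
    width = max(4, len(str(cfg.n)))
    for i in range(cfg.n):
        inside = rng.uniform() < cfg.balance
        desc = _sample_inside_rule(cfg, rng) if inside else _sample_general(cfg, rng)
        smiles = SMILES_POOL[int(rng.integers(len(SMILES_POOL)))]
        rec = _make_record(f"C{i:0{width}d}", desc, smiles, label=None)
        label, _ = planted_rule(rec, cfg.rule)
        if rng.uniform() < cfg.noise:
            label = 1 - label
        records.append(_make_record(rec.id, desc, smiles, label=label))
    manifest = {"generator": "generate_library", "config": _manifest_dict(cfg)}
    return CoformerLibrary(records, metadata=manifest)


def generate_candidate_pool(cfg: GeneratorConfig, size: int) -> CoformerLibrary:
    """Generate an unlabeled candidate pool with one planted optimum.

    The optimum carries the configured tranexamic-acid-like profile and the
    tranexamic acid SMILES; every other record is redrawn (bounded retries)
    until its rule score falls short of the optimum's by at least
    ``cfg.optimum_margin``, making the optimum the strict, unique argmax.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    opt_desc = dict(cfg.optimum_profile)
    opt_rec = _make_record("OPT-0000", opt_desc, TRANEXAMIC_ACID_SMILES, label=None)
    _, opt_score = planted_rule(opt_rec, cfg.rule)

    width = max(4, len(str(size)))
    records: list[CoformerRecord] = []
    for i in range(size - 1):
        for _attempt in range(1000):
            desc = _sample_general(cfg, rng)
            smiles = SMILES_POOL[int(rng.integers(len(SMILES_POOL)))]
            rec = _make_record(f"P{i:0{width}d}", desc, smiles, label=None)
            _, score = planted_rule(rec, cfg.rule)
            if score <= opt_score - cfg.optimum_margin:
                records.append(rec)
                break
        else:
            raise GenerationError(
                f"cannot sample a record scoring below the optimum by {cfg.optimum_margin}"
            )
    pos = int(rng.integers(size))
    records.insert(pos, opt_rec)
    manifest = {
        "generator": "generate_candidate_pool",
        "config": _manifest_dict(cfg),
        "size": size,
        "planted_optimum_id": opt_rec.id,
    }
    return CoformerLibrary(records, metadata=manifest)


def _manifest_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["rule"] = asdict(cfg.rule)
    return d
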