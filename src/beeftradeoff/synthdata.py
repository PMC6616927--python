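"""Synthetic herd generation.

The analysis pipeline in this package was designed around a herd of ~30
finishing heifers on which 62 variables were measured, spanning four
"parameters of interest": Animal Performances (AP), Carcass Properties (CP),
Nutritional Quality of the meat (NQ) and Organoleptic Quality (OQ).  No such
dataset ships with the package, so this module generates statistically
comparable herds from a block factor model:

* every variable belongs to a *block* (a planted cluster) driven by one latent
  block factor ``f_c``;
* variable ``j`` in block ``c`` is ``s_j * (lam_j * f_c +
  sqrt(1 - lam_j**2) * noise_sd * eps_j)`` with ``eps_j`` iid standard normal;
* block factors may receive structural contributions from earlier blocks
  through an acyclic ``cross_links`` map (e.g. carcass fatness depressing the
  PUFA/MUFA balance and boosting flavour intensity), after which each factor
  is renormalised to unit variance;
* the NQ and OQ blocks additionally load on two group-level composite factors
  whose latent correlation ``rho_nq_oq`` is a direct dial for the strength of
  the nutritional/organoleptic association the downstream trade-off analysis
  is supposed to detect.

Colour coordinates are special-cased: redness ``a*`` and yellowness ``b*`` are
generated, while chroma ``C* = sqrt(a*^2 + b*^2)`` and hue
``h* = arctan(b*/a*)`` are derived deterministically afterwards, as a
colorimeter-based dataset would report them.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("AP", "CP", "NQ", "OQ")

__all__ = [
    "GROUPS",
    "ConfigurationError",
    "VariableSpec",
    "BlockSpec",
    "HerdConfig",
    "HerdTable",
    "default_config",
    "generate_herd",
    "derive_color",
]


class ConfigurationError(ValueError):
    """Raised for an invalid herd configuration (bad loading, cyclic links...)."""


@dataclass
class VariableSpec:
    """One measured variable.

    ``loading`` is the correlation-scale weight on the block factor (in [0, 1]),
    ``sign`` orients the variable relative to its block, ``mean``/``scale``
    translate the unit-variance construction into native units, and
    ``derived`` marks columns computed from other columns (chroma, hue) rather
    than sampled.
    """

    name: str
    loading: float = 0.8
    sign: int = 1
    mean: float = 0.0
    scale: float = 1.0
    derived: str | None = None  # None, "chroma" or "hue"


@dataclass
class BlockSpec:
    """A planted cluster of variables sharing one latent factor.

    ``coupling`` is the share of the (pre-link) factor variance contributed by
    the group-level composite factor; blocks with ``coupling = 0`` are
    group-independent.
    """

    name: str
    group: str
    variables: list[VariableSpec]
    coupling: float = 0.0
    # sign of the block's loading on the group composite: +1 for blocks whose
    # factor rises with overall group quality, -1 for "the higher the worse"
    # axes (e.g. the n-6/n-3 ratio within nutritional quality)
    orientation: int = 1


@dataclass
class HerdConfig:
    n_animals: int = 30
    blocks: list[BlockSpec] = field(default_factory=list)
    # (target_block, source_block) -> structural coefficient; the source must
    # be declared before the target (strict lower-triangularity = acyclicity).
    cross_links: dict[tuple[str, str], float] = field(default_factory=dict)
    rho_nq_oq: float = -0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be a positive integer")
        if not -1.0 <= self.rho_nq_oq <= 1.0:
            raise ConfigurationError("rho_nq_oq must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate block names")
        order = {n: i for i, n in enumerate(names)}
        for (tgt, src), coef in self.cross_links.items():
            if tgt not in order or src not in order:
                raise ConfigurationError(f"cross_link references unknown block ({tgt!r}, {src!r})")
            if order[src] >= order[tgt]:
                raise ConfigurationError(
                    f"cross_link {src!r} -> {tgt!r} violates the declared block order "
                    "(links must be strictly lower-triangular / acyclic)"
                )
        seen: set[str] = set()
        for b in self.blocks:
            if b.group not in GROUPS:
                raise ConfigurationError(f"unknown group {b.group!r} in block {b.name!r}")
            if not 0.0 <= b.coupling <= 1.0:
                raise ConfigurationError(f"coupling of block {b.name!r} outside [0, 1]")
            if b.orientation not in (-1, 1):
                raise ConfigurationError(f"orientation of block {b.name!r} must be -1 or +1")
            for v in b.variables:
                if v.name in seen:
                    raise ConfigurationError(f"duplicate variable name {v.name!r}")
                seen.add(v.name)
                if not 0.0 <= v.loading <= 1.0:
                    raise ConfigurationError(
                        f"loading of variable {v.name!r} is {v.loading}, outside [0, 1]"
                    )
                if v.sign not in (-1, 1):
                    raise ConfigurationError(f"sign of variable {v.name!r} must be -1 or +1")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for b in self.blocks for v in b.variables]

    def config_hash(self) -> str:
        h = hashlib.sha256(repr(self).encode())
        return h.hexdigest()[:16]


@dataclass
class HerdTable:
    """Animals x variables table in native units with its group map."""

    values: pd.DataFrame  # rows = animals, columns = variables
    group_map: dict[str, str]  # variable -> AP/CP/NQ/OQ
    provenance: dict
    # latent diagnostics (not part of the observed data):
    factors: pd.DataFrame | None = None  # animals x blocks
    composites: pd.DataFrame | None = None  # animals x groups

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.group_map[c] == group]


def derive_color(a_star, b_star):
    """CIELAB chroma and hue from redness ``a*`` and yellowness ``b*``.

    ``C* = sqrt(a*^2 + b*^2)``; ``h* = arctan(b*/a*)``.  At ``a* = 0`` the hue
    is returned as ``+pi/2 * sign(b*)`` with a warning (the arctan convention
    used throughout this package).  Accepts scalars or arrays.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    chroma = np.sqrt(a**2 + b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        hue = np.arctan(b / a)
    zero = a == 0
    if np.any(zero):
        warnings.warn(
            "a* = 0 encountered: hue set to +/- pi/2 by convention", RuntimeWarning, stacklevel=2
        )
        hue = np.where(zero, np.sign(b) * (math.pi / 2), hue)
    if np.ndim(a_star) == 0 and np.ndim(b_star) == 0:
        return float(chroma), float(hue)
    return chroma, hue


def _factor_coefficients(config: HerdConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact coefficient vectors of block factors over an iid-normal basis.

    Basis layout: [z_AP, z_CP, z_NQ, z_w, eta_block_0, eta_block_1, ...].
    The OQ composite is ``rho * z_NQ + sqrt(1 - rho^2) * z_w`` so that
    corr(g_NQ, g_OQ) = rho exactly.  Structural links are applied in the
    declared block order and each factor is renormalised to unit variance,
    which keeps every factor's population variance exactly 1.
    """
    n_blocks = len(config.blocks)
    n_basis = 4 + n_blocks
    comp = np.zeros((4, n_basis))
    comp[0, 0] = 1.0  # g_AP
    comp[1, 1] = 1.0  # g_CP
    comp[2, 2] = 1.0  # g_NQ
    rho = config.rho_nq_oq
    comp[3, 2] = rho  # g_OQ
    comp[3, 3] = math.sqrt(max(0.0, 1.0 - rho**2))
    gidx = {g: i for i, g in enumerate(GROUPS)}

    coefs = np.zeros((n_blocks, n_basis))
    index = {b.name: i for i, b in enumerate(config.blocks)}
    for i, blk in enumerate(config.blocks):
        c = blk.orientation * math.sqrt(blk.coupling) * comp[gidx[blk.group]]
        c = c + math.sqrt(1.0 - blk.coupling) * np.eye(n_basis)[4 + i]
        for (tgt, src), coef in config.cross_links.items():
            if tgt == blk.name:
                c = c + coef * coefs[index[src]]
        coefs[i] = c / np.linalg.norm(c)
    return coefs, comp, n_basis


def generate_herd(config: HerdConfig | None = None) -> HerdTable:
    """Sample a herd from the block factor model; reproducible given the seed."""
    if config is None:
        config = default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    coefs, comp, n_basis = _factor_coefficients(config)
    n = config.n_animals

    Z = rng.standard_normal((n, n_basis))
    F = Z @ coefs.T  # animals x blocks, unit population variance
    G = Z @ comp.T  # animals x group composites

    columns: dict[str, np.ndarray] = {}
    group_map: dict[str, str] = {}
    derived: list[tuple[VariableSpec, str]] = []
    for i, blk in enumerate(config.blocks):
        for v in blk.variables:
            group_map[v.name] = blk.group
            if v.derived is not None:
                derived.append((v, blk.name))
                columns[v.name] = np.full(n, np.nan)
                continue
            eps = rng.standard_normal(n)
            z = v.sign * (
                v.loading * F[:, i] + math.sqrt(1.0 - v.loading**2) * config.noise_sd * eps
            )
            columns[v.name] = v.mean + v.scale * z

    df = pd.DataFrame(columns, index=pd.RangeIndex(n, name="animal"))

    for v, _blk in derived:
        if v.derived not in ("chroma", "hue"):
            raise ConfigurationError(f"unknown derived kind {v.derived!r} for {v.name!r}")
        if "a_star" not in df.columns or "b_star" not in df.columns:
            raise ConfigurationError("derived colour columns require a_star and b_star variables")
        chroma, hue = derive_color(df["a_star"].to_numpy(), df["b_star"].to_numpy())
        df[v.name] = chroma if v.derived == "chroma" else hue

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_animals": n,
        "rho_nq_oq": config.rho_nq_oq,
        "noise_sd": config.noise_sd,
    }
    factors = pd.DataFrame(F, columns=[b.name for b in config.blocks], index=df.index)
    composites = pd.DataFrame(G, columns=list(GROUPS), index=df.index)
    return HerdTable(df, group_map, provenance, factors=factors, composites=composites)


def default_config(
    n_animals: int = 30,
    rho_nq_oq: float = -0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> HerdConfig:
    """The default 62-variable herd: 3 AP + 20 CP + 28 NQ + 11 OQ.

    Block structure mirrors the cluster narrative the pipeline targets: carcass
    weight travels with bone proportion and pH; the removable fat depots form
    one cluster while inter/intramuscular fatness forms another; ``a*``, ``b*``
    and chroma form one colour cluster and lightness a second; fatty-acid
    variables split into long-chain, C16:0/C18:0, n-6/n-3, PUFA/MUFA, CLA and
    trans families; flavour descriptors split into intensity, bitter,
    rancid-fish, fatty-vs-metal and blood-acid axes.  Cross links encode the
    structural story the analysis should rediscover: fatter carcasses carry
    more intramuscular lipid, a lower PUFA/MUFA balance, more flavour
    intensity, and a tenderness penalty; high PUFA/MUFA promotes rancid-fish
    notes.
    """
    V = VariableSpec
    cw = 0.5  # NQ/OQ group coupling: half composite, half block-specific

    blocks = [
        # --- Carcass Properties (20 variables incl. 2 derived colour columns)
        BlockSpec("CP1", "CP", [
            V("carcass_weight", 0.9, 1, 420.0, 30.0),
            V("bone_proportion", 0.85, -1, 16.0, 1.2),
            V("ph_ultimate", 0.7, 1, 5.55, 0.08),
        ]),
        BlockSpec("CP2", "CP", [
            V("conformation_score", 0.85, 1, 11.0, 1.5),
            V("muscle_proportion", 0.85, 1, 72.0, 2.0),
        ]),
        BlockSpec("CP3", "CP", [
            V("lightness_L", 0.85, 1, 36.0, 2.5),
            V("color_visual_score", 0.8, -1, 2.5, 0.5),
            V("hue_h", derived="hue"),
        ]),
        BlockSpec("CP4", "CP", [
            V("kidney_fat_kg", 0.85, 1, 9.0, 2.0),
            V("pelvic_fat_kg", 0.85, 1, 4.0, 1.0),
            V("trimming_fat_kg", 0.8, 1, 7.0, 1.8),
            V("abdominal_fat_kg", 0.8, 1, 11.0, 2.5),
            V("fifth_quarter_fat_kg", 0.85, 1, 18.0, 3.0),
            V("carcass_fat_weight", 0.85, 1, 30.0, 5.0),
        ]),
        BlockSpec("CP5", "CP", [
            V("fat_proportion", 0.9, 1, 12.0, 2.0),
            V("intermuscular_fat_score", 0.85, 1, 2.5, 0.7),
            V("intramuscular_fat_score", 0.8, 1, 6.0, 1.5),
        ]),
        BlockSpec("CP6", "CP", [
            V("a_star", 0.85, 1, 21.0, 2.5),
            V("b_star", 0.85, 1, 9.0, 1.2),
            V("chroma_C", derived="chroma"),
        ]),
        # --- Animal Performances (3 variables, mutually uncorrelated)
        BlockSpec("AP_sw", "AP", [V("slaughter_weight", 0.9, 1, 693.0, 10.0)]),
        BlockSpec("AP_adg", "AP", [V("adg", 0.9, 1, 1528.0, 53.0)]),
        BlockSpec("AP_fcr", "AP", [V("fcr", 0.9, 1, 0.155, 0.01)]),
        # --- Nutritional Quality (28 variables: lipid content + 27 fatty acid)
        BlockSpec("NQlip", "NQ", [V("lipid_content", 0.9, 1, 2.8, 0.8)]),
        BlockSpec("NQ1", "NQ", [
            V("long_fa_amount", 0.85, 1), V("long_fa_proportion", 0.85, 1),
            V("c22_5n3_dpa", 0.8, 1), V("c22_6n3_dha", 0.8, 1), V("c20_4n6_ara", 0.75, 1),
        ], coupling=cw),
        BlockSpec("NQ2", "NQ", [
            V("c16_c18_ratio", 0.85, 1), V("c14_0", 0.8, 1), V("c18_0", 0.75, -1),
        ], coupling=cw, orientation=-1),
        BlockSpec("NQ3", "NQ", [
            V("n6_n3_ratio", 0.9, 1), V("n6_sum", 0.8, 1), V("n3_sum", 0.85, -1),
            V("sfa_sum", 0.7, 1), V("c16_0", 0.7, 1),
            V("c18_2n6_la", 0.75, 1), V("c18_3n3_lna", 0.8, -1),
        ], coupling=cw, orientation=-1),
        BlockSpec("NQ4", "NQ", [
            V("pufa_mufa_ratio", 0.9, 1), V("pufa_sum", 0.85, 1), V("mufa_sum", 0.85, -1),
            V("c18_1n9_oleic", 0.8, -1), V("pufa_proportion", 0.85, 1),
        ], coupling=cw),
        BlockSpec("NQ5", "NQ", [
            V("cla_total", 0.85, 1), V("cla_c9t11", 0.85, 1), V("cla_t10c12", 0.75, 1),
        ], coupling=cw),
        BlockSpec("NQ6", "NQ", [
            V("trans_fa_total", 0.85, 1), V("c18_1_trans", 0.85, 1),
            V("c18_2_trans", 0.75, 1), V("trans_fa_proportion", 0.8, 1),
        ], coupling=cw, orientation=-1),
        # --- Organoleptic Quality (11 sensory variables, 0-100 panel scale)
        BlockSpec("OQten", "OQ", [V("tenderness", 0.9, 1, 55.0, 12.0)], coupling=cw),
        BlockSpec("OQjui", "OQ", [V("juiciness", 0.9, 1, 50.0, 10.0)], coupling=0.1),
        BlockSpec("OQ1", "OQ", [
            V("flavor_intensity", 0.9, 1, 55.0, 10.0), V("sweet_flavor", 0.75, 1, 20.0, 6.0),
        ], coupling=cw),
        BlockSpec("OQ2", "OQ", [V("bitter_flavor", 0.85, 1, 15.0, 5.0)], coupling=cw,
                  orientation=-1),
        BlockSpec("OQ3", "OQ", [
            V("rancid_flavor", 0.85, 1, 8.0, 4.0), V("fish_flavor", 0.85, 1, 6.0, 3.0),
        ], coupling=cw, orientation=-1),
        BlockSpec("OQ4", "OQ", [
            V("fatty_flavor", 0.85, 1, 25.0, 7.0), V("metallic_flavor", 0.8, -1, 18.0, 5.0),
        ], coupling=cw, orientation=-1),
        BlockSpec("OQ5", "OQ", [
            V("blood_flavor", 0.85, 1, 12.0, 5.0), V("acid_flavor", 0.8, 1, 14.0, 5.0),
        ], coupling=cw, orientation=-1),
    ]

    # Structural links. The coefficients bridging the NQ and OQ groups (through
    # carcass fatness or directly) are kept modest so that rho_nq_oq remains the
    # governing dial for the nutritional/organoleptic association while the
    # fatness relations stay detectable by the models.
    cross_links = {
        ("AP_sw", "CP1"): 0.8,     # slaughter weight tracks carcass weight
        ("NQlip", "CP5"): 0.5,     # fatter carcasses -> more intramuscular lipid
        ("NQ4", "CP5"): -0.35,     # fatter carcasses -> lower PUFA/MUFA
        ("OQ1", "CP5"): 0.35,      # fatter carcasses -> more flavour intensity
        ("OQten", "CP4"): -0.25,   # heavy fat depots -> tenderness penalty
        ("OQ3", "NQ4"): 0.3,       # high PUFA/MUFA -> rancid-fish risk
    }

    cfg = HerdConfig(
        n_animals=n_animals,
        blocks=blocks,
        cross_links=cross_links,
        rho_nq_oq=rho_nq_oq,
        noise_sd=noise_sd,
        seed=seed,
    )
    cfg.validate()
    assert len(cfg.variable_names) == 62
    return cfg
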