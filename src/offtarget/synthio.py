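"""Seeded generators for every synthetic input the workflow consumes.

The package analyses five kinds of experimental data: a stoichiometric
metabolic model, sample x metabolite abundance tables, protein structural
property/pocket tables, OD600 growth curves, chemiluminescence dose-response
tables, and single-cell length samples.  This module fabricates each of them
with known ground truth and full determinism under a fixed seed, so every
downstream statistic can be checked against the parameters that generated it.

The toy metabolic network is folate-centric by design: it is the smallest
model on which the qualitative supplementation-rescue distinctions observed
for an antifolate-like inhibitor can be reproduced —

* thymidine enters pyrimidine synthesis downstream of the folate-dependent
  thymidylate synthase (TMDS) step and rescues a TMDS limitation; uridine
  enters upstream and does not;
* IMP feeds both the adenine and guanine branches of purine synthesis while
  AMP cannot reach the guanine branch (the IMP->AMP step is irreversible and
  the AMP->IMP deaminase is gene-gated off), so after expression shutoffs IMP
  rescues an AICAR-transformylase limitation and AMP does not;
* serine charges the folate cofactor via serine hydroxymethyltransferase
  (SHMT) and rescues a folate-cofactor drain; glycine does not;
* the citrate importer is gene-gated off, removing a spurious carbon-source
  rescue once wild-type expression is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fbarescue import MetabolicModel, Metabolite, Reaction, fba

__all__ = [
    "SynthConfig",
    "ToyModelSpec",
    "MECHANISM_CLASSES",
    "make_toy_model",
    "default_signature_map",
    "simulate_metabolomics",
    "simulate_growth_curve",
    "simulate_dose_response",
    "simulate_structures",
    "simulate_cell_lengths",
]

MECHANISM_CLASSES = (
    "antifolate",
    "cell_wall",
    "dna_synthesis",
    "translation",
    "oxidative_stress",
)


@dataclass
class SynthConfig:
    """Shared knobs for the metabolomics generator.

    noise_sd is the standard deviation of multiplicative log-normal noise on
    the natural-log scale; effect_size is the log2 fold-change magnitude of a
    perturbed metabolite.  Defaults: triplicates and three harvest points
    (early lag, mid-exponential, late log) as in a typical treated-vs-control
    time course, noise small relative to the class signatures.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_sd: float = 0.2
    effect_size: float = 3.0
    class_labels: tuple[str, ...] = MECHANISM_CLASSES
    time_points: tuple[float, ...] = (0.0, 0.5, 4.0, 12.0)
    low_score_fraction: float = 0.3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class ToyModelSpec:
    """Layout of the toy folate-centric network (ids are fixed topology)."""

    glucose_uptake: float = 10.0
    serine_synthesis_cap: float = 7.0
    folate_cycle: dict = field(default_factory=lambda: {
        "charging": ["SHMT"],
        "discharging": ["TMDS", "AICART"],
        "charged": "mlthf",
        "discharged": "thf",
    })
    branch_map: dict = field(default_factory=lambda: {
        "purine": ["PURSYN", "AICART"],
        "pyrimidine": ["PYRSYN", "ORO2UMP", "UMP2DUMP", "TMDS"],
        "serine_glycine": ["SERSYN", "SHMT"],
    })
    transporter_map: dict = field(default_factory=lambda: {
        "thymidine": "EX_thymidine_e",
        "uridine": "EX_uridine_e",
        "imp": "EX_imp_e",
        "amp": "EX_amp_e",
        "serine": "EX_serine_e",
        "glycine": "EX_glycine_e",
        "aspartate": "EX_aspartate_e",
        "citrate": "EX_citrate_e",
    })
    unexpressed_genes: tuple[str, ...] = ("adeD", "citT")


def make_toy_model(spec: ToyModelSpec | None = None) -> MetabolicModel:
    """Build the toy folate-centric stoichiometric model.

    Glucose is the sole default carbon source (uptake bounded at
    spec.glucose_uptake); the biomass objective consumes dTMP, dATP, dGTP,
    serine, glycine, aspartate and generic carbon.  The folate cofactor
    cycles between thf (discharged) and mlthf (charged) — charged by SHMT,
    discharged by TMDS and AICART — so folate limitation propagates to both
    nucleotide branches.
    """
    spec = spec or ToyModelSpec()
    if spec.glucose_uptake <= 0:
        raise ValueError("glucose_uptake must be positive")

    ext = ["glucose", "thymidine", "uridine", "imp", "amp",
           "serine", "glycine", "aspartate", "citrate"]
    internal = ["glc", "carbon", "ser", "gly", "asp", "cit", "thym", "urd",
                "orot", "ump", "dump", "dtmp", "aicar", "imp", "amp", "gmp",
                "datp", "dgtp", "dhf", "thf", "mlthf"]
    mets = [Metabolite(f"{m}_e", "e") for m in ext]
    mets += [Metabolite(m, "c") for m in internal]

    R = Reaction
    rxns = [
        # exchanges: uptake negative; only glucose open by default
        R("EX_glucose_e", {"glucose_e": -1}, -spec.glucose_uptake, 1000),
        R("EX_thymidine_e", {"thymidine_e": -1}, 0, 1000),
        R("EX_uridine_e", {"uridine_e": -1}, 0, 1000),
        R("EX_imp_e", {"imp_e": -1}, 0, 1000),
        R("EX_amp_e", {"amp_e": -1}, 0, 1000),
        R("EX_serine_e", {"serine_e": -1}, 0, 1000),
        R("EX_glycine_e", {"glycine_e": -1}, 0, 1000),
        R("EX_aspartate_e", {"aspartate_e": -1}, 0, 1000),
        R("EX_citrate_e", {"citrate_e": -1}, 0, 1000),
        # transporters
        R("GLCt", {"glucose_e": -1, "glc": 1}, 0, 1000, gene_rule="ptsG"),
        R("THYMt", {"thymidine_e": -1, "thym": 1}, 0, 1000, gene_rule="nupC"),
        R("URDt", {"uridine_e": -1, "urd": 1}, 0, 1000, gene_rule="nupC"),
        R("IMPt", {"imp_e": -1, "imp": 1}, 0, 1000, gene_rule="nupG"),
        # AMP has no dedicated importer; its entry runs through uncatalyzed
        # periplasmic dephosphorylation/rephosphorylation, modelled as a
        # spontaneous transport step
        R("AMPt", {"amp_e": -1, "amp": 1}, 0, 1000, spontaneous=True),
        R("SERt", {"serine_e": -1, "ser": 1}, 0, 1000, gene_rule="sdaC"),
        R("GLYt", {"glycine_e": -1, "gly": 1}, 0, 1000, gene_rule="cycA"),
        R("ASPt", {"aspartate_e": -1, "asp": 1}, 0, 1000, gene_rule="gltP"),
        R("CITt", {"citrate_e": -1, "cit": 1}, 0, 1000, gene_rule="citT"),
        # central carbon
        R("GLYC", {"glc": -1, "carbon": 2}, 0, 1000, gene_rule="pgi"),
        R("CITLY", {"cit": -1, "carbon": 2}, 0, 1000, gene_rule="gltA"),
        R("SERSYN", {"carbon": -1, "ser": 1}, 0, spec.serine_synthesis_cap,
          gene_rule="serA"),
        # folate-independent glycine route (threonine aldolase-like), so
        # glycine supply is not rigidly coupled to SHMT byproduct flux
        R("GLYSYN", {"carbon": -1, "gly": 1}, 0, 1000, gene_rule="ltaE"),
        R("ASPSYN", {"carbon": -1, "asp": 1}, 0, 1000, gene_rule="aspC"),
        # pyrimidine branch: folate-dependent TMDS, thymidine salvage below it
        R("PYRSYN", {"carbon": -1, "asp": -1, "orot": 1}, 0, 1000, gene_rule="pyrB"),
        R("ORO2UMP", {"orot": -1, "ump": 1}, 0, 1000, gene_rule="pyrE"),
        R("URD2UMP", {"urd": -1, "ump": 1}, 0, 1000, gene_rule="udk"),
        R("UMP2DUMP", {"ump": -1, "dump": 1}, 0, 1000, gene_rule="ndk"),
        R("TMDS", {"dump": -1, "mlthf": -1, "dtmp": 1, "dhf": 1}, 0, 1000,
          gene_rule="thyA"),
        R("THYMSALV", {"thym": -1, "dtmp": 1}, 0, 1000, gene_rule="tdk"),
        # purine branch: folate-dependent AICART; IMP feeds both end branches,
        # AMP is stranded (irreversible IMP2AMP; deaminase gene-gated;
        # AMP->dATP incorporation spontaneous)
        R("PURSYN", {"carbon": -2, "gly": -1, "aicar": 1}, 0, 1000, gene_rule="purF"),
        R("AICART", {"aicar": -1, "mlthf": -1, "imp": 1, "thf": 1}, 0, 1000,
          gene_rule="purH"),
        R("IMP2AMP", {"imp": -1, "amp": 1}, 0, 1000, gene_rule="purA"),
        R("IMP2GMP", {"imp": -1, "gmp": 1}, 0, 1000, gene_rule="guaB"),
        R("AMPDA", {"amp": -1, "imp": 1}, 0, 1000, gene_rule="adeD"),
        R("AMP2DATP", {"amp": -1, "datp": 1}, 0, 1000, gene_rule="ndk"),
        R("GMP2DGTP", {"gmp": -1, "dgtp": 1}, 0, 1000, gene_rule="ndk"),
        # folate cycle
        R("SHMT", {"ser": -1, "thf": -1, "gly": 1, "mlthf": 1}, 0, 1000,
          gene_rule="glyA"),
        R("DHFR", {"dhf": -1, "thf": 1}, 0, 1000, gene_rule="folA"),
        R("FOLSYN", {"carbon": -1, "dhf": 1}, 0, 1000, gene_rule="folK and folP"),
        R("GLYSINK", {"gly": -1}, 0, 1000),
        # biomass
        R("BIOMASS", {"dtmp": -1, "datp": -1, "dgtp": -1, "ser": -1,
                      "gly": -1, "asp": -1, "carbon": -2},
          0, 1000, objective_coefficient=1.0),
    ]
    model = MetabolicModel(id="toy_folate", metabolites=mets, reactions=rxns)
    model.validate()
    _validate_spec_against_model(spec, model)
    return model


def _validate_spec_against_model(spec: ToyModelSpec, model: MetabolicModel) -> None:
    rids = set(model.reaction_ids())
    for supp, ex in spec.transporter_map.items():
        if ex not in rids:
            raise ValueError(f"supplement {supp!r} has no exchange {ex!r} in the model")
    for group in spec.branch_map.values():
        missing = set(group) - rids
        if missing:
            raise ValueError(f"branch_map references unknown reactions {sorted(missing)}")
    if not fba(model, parsimonious=False).objective_value > 0:
        raise ValueError("toy model baseline FBA optimum is not positive")


# ---------------------------------------------------------------------------
# Metabolomics
# ---------------------------------------------------------------------------

def default_signature_map(
    class_labels=MECHANISM_CLASSES,
    n_metabolites: int = 40,
    effect_size: float = 3.0,
    n_perturbed: int = 8,
    seed: int = 7,
) -> pd.DataFrame:
    """Per-class log2 effect vectors over a shared metabolite namespace.

    Each mechanism class perturbs its own block of metabolites (half up,
    half down) by +/- effect_size, with one metabolite shared between
    consecutive classes so signatures overlap as real mechanism signatures do.
    """
    rng = np.random.default_rng(seed)
    mets = [f"M{i:03d}" for i in range(n_metabolites)]
    sig = pd.DataFrame(0.0, index=list(class_labels), columns=mets)
    block = max(1, (n_metabolites - 1) // max(len(class_labels), 1))
    for ci, cls in enumerate(class_labels):
        start = (ci * block) % n_metabolites
        idx = [(start + j) % n_metabolites for j in range(n_perturbed)]
        signs = rng.choice([-1.0, 1.0], size=n_perturbed)
        for j, s in zip(idx, signs):
            sig.iloc[ci, j] = s * effect_size
    return sig


def simulate_metabolomics(
    config: SynthConfig,
    signature_map: pd.DataFrame | None = None,
    baseline: float = 1e6,
):
    """Simulate a treated-vs-control abundance panel.

    Each sample's intensity is baseline x 2^(class effect) x exp(N(0, sd)).
    Returns (AbundanceTable, labels) where labels maps each treated condition
    to its mechanism class; the control condition carries zero effect.  A
    configurable fraction of metabolites receives annotation score <= 50 to
    exercise confidence filtering downstream.
    """
    from .metabstats import AbundanceTable  # local import to avoid cycle

    if signature_map is None:
        signature_map = default_signature_map(
            config.class_labels, effect_size=config.effect_size, seed=config.seed + 101
        )
    if signature_map.shape[0] == 0:
        raise ValueError("signature_map has no classes")
    rng = np.random.default_rng(config.seed)
    mets = list(signature_map.columns)

    conditions = ["control"] + list(signature_map.index)
    labels = {c: c for c in signature_map.index}
    rows, meta = [], []
    for cond in conditions:
        effect = (signature_map.loc[cond].to_numpy()
                  if cond != "control" else np.zeros(len(mets)))
        for t in config.time_points:
            # perturbation absent at time zero (pre-treatment harvest)
            eff = effect if t > 0 else np.zeros_like(effect)
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, config.noise_sd, size=len(mets))
                rows.append(baseline * np.power(2.0, eff) * np.exp(noise))
                meta.append({"sample": f"{cond}_t{t:g}_r{rep}", "condition": cond,
                             "time_point": t, "replicate": rep})
    sample_meta = pd.DataFrame(meta).set_index("sample")
    intensities = pd.DataFrame(rows, index=sample_meta.index, columns=mets)

    n_low = int(round(config.low_score_fraction * len(mets)))
    scores = np.full(len(mets), 0.0)
    scores[:] = rng.uniform(51, 100, size=len(mets))
    low_idx = rng.choice(len(mets), size=n_low, replace=False)
    scores[low_idx] = rng.uniform(0, 50, size=n_low)
    metabolite_meta = pd.DataFrame(
        {"annotation_score": np.round(scores, 1)}, index=mets
    )
    table = AbundanceTable(intensities, sample_meta, metabolite_meta)
    return table, labels


# ---------------------------------------------------------------------------
# Growth curves, dose-response, structures, cell lengths
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    r: float,
    lag: float,
    K: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 15.0,
    dt: float = 0.5,
) -> pd.DataFrame:
    """Three-parameter logistic OD600 curve sampled every 30 min over 15 h.

    OD(t) = K / (1 + exp(-r (t - t_mid))) with the inflection placed so the
    tangent-intercept lag equals `lag` (t_mid = lag + 2/r), plus additive
    Gaussian noise.  Returns a DataFrame with columns time_h, od600.
    """
    if r <= 0:
        raise ValueError("growth rate must be positive")
    if K <= 0:
        raise ValueError("carrying capacity must be positive")
    t = np.arange(0.0, t_max + 1e-9, dt)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    t_mid = lag + 2.0 / r
    od = K / (1.0 + np.exp(-r * (t - t_mid)))
    if noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    od = np.clip(od, 0.0, None)
    return pd.DataFrame({"time_h": t, "od600": od})


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top_signal: float = 4.0e5,
    floor_signal: float = 0.5e5,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Chemiluminescence vs inhibitor concentration for an ATP-consuming assay.

    Inhibition spares ATP, so the luminescence signal RISES with inhibitor:
    floor_signal at zero inhibitor (full reaction) up to top_signal at
    saturating inhibitor (no reaction).  Returns columns conc_um, signal.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if floor_signal >= top_signal:
        raise ValueError("floor_signal must be below top_signal")
    if concentrations is None:
        concentrations = np.array([0.0] + list(ic50 * np.logspace(-2, 2, 9)))
    conc = np.asarray(concentrations, dtype=float)
    if not np.any(conc == 0):
        raise ValueError("concentrations must include 0 (zero-inhibitor reference)")
    frac = np.where(conc > 0, conc**hill / (ic50**hill + conc**hill), 0.0)
    signal = floor_signal + (top_signal - floor_signal) * frac
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, conc.size)
    out = pd.DataFrame({"conc_um": conc, "signal": signal})
    # the assay's enzyme-free control well (maximum luminescence reference)
    out.attrs["no_reaction_signal"] = float(top_signal)
    return out


def simulate_structures(
    n_proteins: int = 20,
    n_properties: int = 12,
    pocket_universe_bits: int = 64,
    related_group: dict | None = None,
    seed: int = 0,
    pockets_per_protein: int = 5,
    bits_per_pocket: int = 16,
):
    """Synthetic global-property matrix and binding-pocket fingerprints.

    related_group maps protein id -> target bit overlap (Jaccard-like
    fraction) with the reference protein's largest pocket; the reference is
    the first key.  Every protein carries exactly `pockets_per_protein`
    pockets.  Returns (properties: DataFrame, pockets: DataFrame with columns
    protein_id, pocket_id, size, bits).
    """
    if n_proteins < 2:
        raise ValueError("need at least two proteins")
    rng = np.random.default_rng(seed)
    related_group = related_group or {}
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    for i, pid in enumerate(related_group):
        proteins[i] = pid

    props = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_proteins, n_properties)),
        index=proteins,
        columns=[f"prop_{j}" for j in range(n_properties)],
    )

    ref_bits = rng.choice(pocket_universe_bits, size=bits_per_pocket, replace=False)
    rows = []
    for pid in proteins:
        overlap = related_group.get(pid)
        for k in range(pockets_per_protein):
            if overlap is not None and k == 0:
                n_shared = int(round(overlap * bits_per_pocket))
                shared = rng.choice(ref_bits, size=n_shared, replace=False)
                rest_pool = np.setdiff1d(np.arange(pocket_universe_bits), ref_bits)
                rest = rng.choice(rest_pool, size=bits_per_pocket - n_shared,
                                  replace=False)
                bits = np.concatenate([shared, rest])
            else:
                bits = rng.choice(pocket_universe_bits, size=bits_per_pocket,
                                  replace=False)
            rows.append({
                "protein_id": pid,
                "pocket_id": f"{pid}_pk{k}",
                "size": int(300 - 40 * k + rng.integers(0, 20)),
                "bits": " ".join(str(b) for b in sorted(int(b) for b in bits)),
            })
    # the reference's own first pocket must be exactly ref_bits
    ref = proteins[0] if related_group else proteins[0]
    rows[0]["bits"] = " ".join(str(int(b)) for b in sorted(ref_bits))
    pockets = pd.DataFrame(rows)
    return props, pockets


def simulate_cell_lengths(
    median_a: float,
    median_b: float,
    n: int = 300,
    seed: int = 0,
    sigma: float = 0.3,
    min_length: float = 0.5,
):
    """Two log-normal cell-length samples (um) with specified medians.

    Values below min_length are resampled, emulating the resolution floor of
    DIC imaging.  Returns (sample_a, sample_b) as numpy arrays of length n.
    """
    if median_a <= 0 or median_b <= 0:
        raise ValueError("medians must be positive")
    rng = np.random.default_rng(seed)

    def draw(median):
        out = np.empty(0)
        while out.size < n:
            x = rng.lognormal(np.log(median), sigma, size=2 * n)
            out = np.concatenate([out, x[x >= min_length]])
        return out[:n]

    return draw(median_a), draw(median_b)
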