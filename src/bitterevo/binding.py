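"""Key binding-site positions and the strychnine-binding rule engine.

Human bitter taste receptors T2R10 and T2R46 recognize strychnine through
two distinct binding modes.  Site-directed mutagenesis has identified, for
each receptor, a set of *key positions* (in Ballesteros-Weinstein numbering)
whose substitution tolerates, reduces, or abolishes activation.  This module
ships that catalog as data and evaluates arbitrary residue combinations
against it, yielding a four-level verdict per binding mode:

``binder``           every key residue is present;
``reduced_binder``   only substitutions known (or inferred) to be tolerated
                     or to reduce sensitivity;
``uncertain``        at least one substitution of unknown effect (including
                     chemically similar replacements whose impact cannot be
                     predicted), and nothing that abolishes binding;
``non_binder``       any substitution known to abolish activation, or at
                     least two non-conservative changes at critical
                     positions.

The overall verdict is the best of the two mode verdicts.  Effect rules are
matched in catalog order (first match wins); a substitution with no matching
rule has unknown effect.  Reconstructed ancestral residues may carry tied
predictions ("T/A"); a tie that includes the key residue contributes a
*reduced* effect (the functional residue is plausibly present but its
conservation is not certain), and a tie without it contributes the worst
effect among the alternatives.

Property classes used by class-based rules: charge negative {D,E}, positive
{K,R,H}, neutral otherwise; hydropathy by the Kyte-Doolittle scale with
threshold 0 (hydrophobic: A,C,F,I,L,M,V); side-chain volume small (< 120
cubic angstroms), medium (120-170), large (> 170).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Iterable, Mapping

# -- residue property classes ------------------------------------------------

NEGATIVE = set("DE")
POSITIVE = set("KRH")
HYDROPHOBIC = set("ACFILMV")  # Kyte-Doolittle > 0

# side-chain volumes (cubic angstroms)
_VOLUME = {
    "G": 60, "A": 89, "S": 89, "C": 109, "D": 111, "P": 113, "N": 114,
    "T": 116, "E": 138, "V": 140, "Q": 144, "H": 153, "M": 163, "I": 167,
    "L": 167, "K": 169, "R": 174, "F": 190, "Y": 194, "W": 228,
}
_VOLUME_CLASS = {a: ("small" if v < 120 else "medium" if v <= 170 else "large")
                 for a, v in _VOLUME.items()}

VERDICT_ORDER = ["non_binder", "uncertain", "reduced_binder", "binder"]
EFFECT_SEVERITY = {"tolerated": 0, "reduced": 1, "unknown": 2, "abolished": 3}


def charge_class(aa: str) -> str:
    return "neg" if aa in NEGATIVE else "pos" if aa in POSITIVE else "neutral"


def hydropathy_class(aa: str) -> str:
    return "hydrophobic" if aa in HYDROPHOBIC else "hydrophilic"


def volume_class(aa: str) -> str:
    return _VOLUME_CLASS[aa]


def chemically_similar(a: str, b: str) -> bool:
    """Same charge class, same hydropathy class, and side-chain volume within
    one class step (e.g. V/I, M/I, T/S, L/F)."""
    if a == b:
        return True
    if a not in _VOLUME or b not in _VOLUME:
        return False
    steps = {"small": 0, "medium": 1, "large": 2}
    return (
        charge_class(a) == charge_class(b)
        and hydropathy_class(a) == hydropathy_class(b)
        and abs(steps[volume_class(a)] - steps[volume_class(b)]) <= 1
    )


# -- catalog -----------------------------------------------------------------

@dataclasses.dataclass
class EffectRule:
    """One ordered substitution rule: an explicit residue or a property
    class, the assay-derived (or inferred) effect, and a citation tag."""

    substitution_class: str  # e.g. "K", "charge:pos", "hydropathy:hydrophobic"
    effect: str              # tolerated | reduced | abolished | unknown
    source: str = ""

    def matches(self, observed: str) -> bool:
        sc = self.substitution_class
        if ":" not in sc:
            return observed == sc
        kind, value = sc.split(":", 1)
        if kind == "charge":
            return charge_class(observed) == value
        if kind == "hydropathy":
            return hydropathy_class(observed) == value
        if kind == "volume":
            return volume_class(observed) == value
        raise ValueError(f"unknown substitution class {sc!r}")


@dataclasses.dataclass
class KeyPosition:
    bw_label: str
    mode: str                # "R10" | "R46"
    key_residue: str
    criticality: str         # "critical" | "supporting"
    effect_rules: list[EffectRule]

    def effect_of(self, observed: str) -> str:
        if observed == self.key_residue:
            return "match"
        if observed not in _VOLUME:  # gap, X, or other non-standard symbol
            return "unknown"
        for rule in self.effect_rules:
            if rule.matches(observed):
                return rule.effect
        return "unknown"


@dataclasses.dataclass
class KeyPositionCatalog:
    entries: list[KeyPosition]

    def for_mode(self, mode: str) -> list[KeyPosition]:
        return [e for e in self.entries if e.mode == mode]

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.bw_label, None)
        return list(seen)

    def key_residues(self, mode: str) -> dict[str, str]:
        return {e.bw_label: e.key_residue for e in self.for_mode(mode)}

    def validate(self) -> None:
        n10 = len(self.for_mode("R10"))
        n46 = len(self.for_mode("R46"))
        labels = set(self.labels)
        shared = {e.bw_label for e in self.for_mode("R10")} & \
                 {e.bw_label for e in self.for_mode("R46")}
        if (n10, n46, len(labels), len(shared)) != (12, 15, 20, 7):
            raise ValueError(
                "catalog does not match the expected key-position counts "
                f"(R10={n10}, R46={n46}, union={len(labels)}, shared={len(shared)}; "
                "expected 12/15/20/7) -- fixture corrupted?"
            )


def load_catalog(path: str | Path | None = None) -> KeyPositionCatalog:
    """Load the key-position catalog (bundled by default) and validate the
    expected counts: 12 T2R10-mode entries, 15 T2R46-mode entries, 20
    distinct positions of which 7 carry both modes."""
    if path is None:
        text = importlib.resources.files("bitterevo.data").joinpath(
            "key_position_catalog.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    entries = []
    for e in raw["entries"]:
        rules = [EffectRule(r["sub"], r["effect"], r.get("source", ""))
                 for r in e.get("rules", [])]
        entries.append(KeyPosition(
            bw_label=e["bw"], mode=e["mode"], key_residue=e["key"],
            criticality=e.get("criticality", "supporting"), effect_rules=rules,
        ))
    catalog = KeyPositionCatalog(entries=entries)
    catalog.validate()
    return catalog


# -- conservation counting ---------------------------------------------------

def _primary(residue: str) -> str:
    return residue.split("/")[0]


def _alternatives(residue: str) -> list[str]:
    return residue.split("/")


def conserved_count(
    residues: Mapping[str, str],
    catalog: KeyPositionCatalog,
    mode: str = "both",
) -> tuple[int, int, list[dict]]:
    """Count key positions whose (primary) residue matches the key residue.

    ``mode="both"`` scores all 20 positions, counting a position conserved
    when it matches the key residue of *any* mode defined there.  Returns
    ``(n_conserved, n_total, details)`` where details list the mismatches
    with a chemical-similarity flag.
    """
    if mode == "both":
        keys: dict[str, set[str]] = {}
        for e in catalog.entries:
            keys.setdefault(e.bw_label, set()).add(e.key_residue)
    else:
        keys = {lab: {res} for lab, res in catalog.key_residues(mode).items()}
    missing = [lab for lab in keys if lab not in residues]
    if missing:
        raise KeyError(f"residues missing for catalog positions: {missing}")
    n_cons = 0
    details: list[dict] = []
    for lab, wanted in keys.items():
        obs = _primary(residues[lab])
        if obs in wanted:
            n_cons += 1
        else:
            details.append({
                "bw_label": lab,
                "observed": residues[lab],
                "key": "/".join(sorted(wanted)),
                "chemically_similar": any(chemically_similar(obs, k) for k in wanted),
            })
    return n_cons, len(keys), details


# -- binder classification ---------------------------------------------------

@dataclasses.dataclass
class BinderCall:
    verdict: str
    mode_verdicts: dict[str, str]
    evidence: list[dict]     # per mismatch: mode, bw_label, observed, key, effect

    def __post_init__(self) -> None:
        best = max(self.mode_verdicts.values(), key=VERDICT_ORDER.index)
        if self.verdict != best:
            raise ValueError("verdict must be the best of the mode verdicts")


def _position_effect(entry: KeyPosition, observed: str) -> str:
    """Effect of the observed residue(s) at one key position.  Tied
    reconstructions including the key residue soften to 'reduced'."""
    alts = _alternatives(observed)
    if len(alts) == 1:
        eff = entry.effect_of(alts[0])
        return eff
    if entry.key_residue in alts:
        return "reduced"
    effs = [entry.effect_of(a) for a in alts]
    effs = [e for e in effs if e != "match"]
    return max(effs, key=lambda e: EFFECT_SEVERITY[e])


def classify_binder(
    residues: Mapping[str, str],
    catalog: KeyPositionCatalog,
) -> BinderCall:
    """Four-level strychnine-binding verdict for one residue combination.

    ``residues`` maps BW labels to residues (ties as "T/A"); all catalog
    positions must be covered.  Both binding modes are evaluated; the
    overall verdict is the better one.
    """
    mode_verdicts: dict[str, str] = {}
    evidence: list[dict] = []
    for mode in ("R10", "R46"):
        entries = catalog.for_mode(mode)
        missing = [e.bw_label for e in entries if e.bw_label not in residues]
        if missing:
            raise KeyError(f"residues missing for {mode} positions: {missing}")
        effects: list[str] = []
        n_critical_noncons = 0
        for e in entries:
            obs = residues[e.bw_label]
            eff = _position_effect(e, obs)
            if eff == "match":
                continue
            effects.append(eff)
            evidence.append({
                "mode": mode, "bw_label": e.bw_label, "observed": obs,
                "key": e.key_residue, "criticality": e.criticality, "effect": eff,
            })
            primary = _primary(obs)
            if (e.criticality == "critical" and primary != e.key_residue
                    and e.key_residue not in _alternatives(obs)
                    and not chemically_similar(primary, e.key_residue)):
                n_critical_noncons += 1
        if any(eff == "abolished" for eff in effects) or n_critical_noncons >= 2:
            verdict = "non_binder"
        elif any(eff == "unknown" for eff in effects):
            verdict = "uncertain"
        elif effects:
            verdict = "reduced_binder"
        else:
            verdict = "binder"
        mode_verdicts[mode] = verdict
    overall = max(mode_verdicts.values(), key=VERDICT_ORDER.index)
    return BinderCall(verdict=overall, mode_verdicts=mode_verdicts, evidence=evidence)


# -- bundled residue fixtures -------------------------------------------------

def load_reference_residues(name: str = "table1_key_residues.tsv") -> dict[str, dict[str, str]]:
    """Bundled key-residue matrices (column name -> {bw_label: residue}).

    ``table1_key_residues.tsv`` transcribes the published matrix of key-
    position residues for hT2R10, hT2R46, and selected reconstructed
    ancestors; ``species_key_variants.tsv`` carries per-species variant
    lists from the published per-species figures.
    """
    text = importlib.resources.files("bitterevo.data").joinpath(name).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    out: dict[str, dict[str, str]] = {col: {} for col in header}
    for line in lines[1:]:
        parts = line.split("\t")
        lab = parts[0]
        for col, val in zip(header, parts[1:]):
            out[col][lab] = val
    return out


def load_species_variants() -> dict[str, dict]:
    """Per-species key-residue variant fixtures: species tag ->
    {mode, variations: {bw_label: residue}}."""
    text = importlib.resources.files("bitterevo.data").joinpath(
        "species_key_variants.tsv").read_text()
    out: dict[str, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        species, mode, variations = parts[0], parts[1], (parts[2] if len(parts) > 2 else "")
        var: dict[str, str] = {}
        if variations:
            for item in variations.split(","):
                lab, res = item.split(":")
                var[lab] = res
        out[species] = {"mode": mode, "variations": var}
    return out


def species_residue_map(species: str, catalog: KeyPositionCatalog,
                        reference: Mapping[str, Mapping[str, str]],
                        variants: Mapping[str, dict]) -> dict[str, str]:
    """Full 20-position residue map for a fixture species: the human
    reference residues of its clade with the recorded variants applied."""
    info = variants[species]
    base_col = "hT2R10" if info["mode"] == "R10" else "hT2R46"
    residues = dict(reference[base_col])
    residues.update(info["variations"])
    return residues
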