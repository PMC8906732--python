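"""Pluggable photophysics evaluators.

Three pieces live here:

* A deterministic closed-form **surrogate** mapping structural descriptors to
  a photophysical profile.  It is the evaluator used throughout the test
  suite and for desk-scale search experiments: absorption red-shifts with
  conjugation length and ring count, intensity saturates with conjugation,
  fluorescence is Stokes-shifted and damped by rings.
* A **TD-DFT adapter**: a quantum-chemistry input-deck writer (route section,
  charge/multiplicity, Cartesian block) and an excited-state log parser.
  The QC engine itself is never executed here; real deployments plug an
  engine behind the same evaluator contract.
* A caching wrapper keyed by canonical SMILES so duplicate molecules are
  never re-evaluated and evaluator failures degrade to an
  ``evaluation_failed`` profile instead of aborting the search.

Energies convert to wavelengths via hc = 1239.84193 eV nm.
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass
from typing import Callable

from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import InputError, TDLogParseError
from .molecule_io import Molecule
from .reward import PhotophysicalProfile

HC_EV_NM = 1239.84193  # Planck constant times speed of light, eV·nm

STAGE_S0 = "s0_opt_td"
STAGE_S1 = "s1_opt_td"


@dataclass(frozen=True)
class QCJobSpec:
    """One excited-state calculation request.

    ``stage`` distinguishes the ground-state-minimum TD run (absorption)
    from the S1-optimization TD run (fluorescence).
    """

    method: str = "B3LYP/3-21G*"
    n_states: int = 10
    stage: str = STAGE_S0
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise InputError("n_states must be >= 1")
        if self.stage not in (STAGE_S0, STAGE_S1):
            raise InputError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class ExcitationRecord:
    """One excited state: index, energy (eV), wavelength (nm), OS."""

    state: int
    energy_ev: float
    wavelength_nm: float
    osc_strength: float

    def __post_init__(self) -> None:
        if self.energy_ev <= 0:
            raise InputError("excitation energy must be positive")


Evaluator = Callable[[Molecule], PhotophysicalProfile]


# ---------------------------------------------------------------------------
# surrogate

def surrogate_evaluate(mol: Molecule) -> PhotophysicalProfile:
    """Deterministic closed-form profile from structural descriptors.

    With L the conjugate length, A the aromatic ring count and N the
    nitrogen count:

        a_w = 150 + 55 L + 15 A           (nm)
        a_i = 1 - exp(-0.15 (L + 1))
        f_w = a_w + 40 + 10 N             (nm; always Stokes-shifted)
        f_i = a_i exp(-0.1 A)

    The form is fixed for all tests; it reproduces the qualitative trend
    that conjugation elongation red-shifts and brightens absorption.
    """
    L = mol.conjugate_length
    A = mol.n_aromatic_rings
    N = mol.element_count("N")
    a_w = 150.0 + 55.0 * L + 15.0 * A
    a_i = 1.0 - math.exp(-0.15 * (L + 1))
    f_w = a_w + 40.0 + 10.0 * N
    f_i = a_i * math.exp(-0.1 * A)
    return PhotophysicalProfile(a_w=a_w, a_i=a_i, f_w=f_w, f_i=f_i)


class CachedEvaluator:
    """Memoizing, failure-absorbing wrapper around an evaluator.

    Results are cached by canonical SMILES; any exception from the inner
    evaluator becomes an ``evaluation_failed`` profile (the search must
    never be aborted by a single bad molecule).
    """

    def __init__(self, inner: Evaluator):
        self.inner = inner
        self.cache: dict[str, PhotophysicalProfile] = {}
        self.n_calls = 0  # inner-evaluator invocations, not lookups

    def __call__(self, mol: Molecule) -> PhotophysicalProfile:
        key = mol.smiles_canonical
        if key in self.cache:
            return self.cache[key]
        try:
            self.n_calls += 1
            profile = self.inner(mol)
        except Exception:
            profile = PhotophysicalProfile.failed()
        self.cache[key] = profile
        return profile

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.cache


def evaluate(mol: Molecule, oracle: Evaluator) -> PhotophysicalProfile:
    """Evaluate ``mol`` with ``oracle``; never raises into the search loop."""
    try:
        return oracle(mol)
    except Exception:
        return PhotophysicalProfile.failed()


# ---------------------------------------------------------------------------
# 3D embedding and input decks

def embed_coordinates(mol: Molecule) -> list[tuple[str, float, float, float]]:
    """One deterministic 3D embedding per canonical SMILES.

    The ETKDG embedding seed is derived from the canonical SMILES, so the
    same structure always yields byte-identical coordinates regardless of
    input spelling.  Hydrogens are made explicit for the QC deck.
    """
    rdmol = Chem.AddHs(Chem.MolFromSmiles(mol.smiles_canonical))
    seed = zlib.crc32(mol.smiles_canonical.encode()) & 0x7FFFFFFF
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise InputError(f"3D embedding failed for {mol.smiles_canonical!r}")
    conf = rdmol.GetConformer()
    return [
        (atom.GetSymbol(), *conf.GetAtomPosition(atom.GetIdx()))
        for atom in rdmol.GetAtoms()
    ]


def write_td_dft_input(coords: list[tuple[str, float, float, float]],
                       spec: QCJobSpec = QCJobSpec()) -> str:
    """Render a QC input deck (route, title, charge/multiplicity, Cartesians).

    The S1 stage requests excited-state geometry optimization of state 1.
    Bit-exact for identical inputs.
    """
    if not coords:
        raise InputError("no coordinates supplied")
    td = f"TD(NStates={spec.n_states})"
    if spec.stage == STAGE_S1:
        td = f"TD(NStates={spec.n_states},Root=1) Opt"
    lines = [
        f"# {spec.method} {td}",
        "",
        f"fluoromcts {spec.stage} job",
        "",
        f"{spec.charge} {spec.multiplicity}",
    ]
    for symbol, x, y, z in coords:
        lines.append(f" {symbol:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# TD-DFT log parsing

_STATE_RE = re.compile(
    r"Excited State\s+(\d+):\s+\S+\s+(\S+)\s*eV\s+(\S+)\s*nm\s+f=(\S+)"
)


def render_td_dft_log(blocks: list[list[ExcitationRecord]]) -> str:
    """Render a synthetic TD-DFT log from known excitation records.

    Used to build test fixtures (and the round-trip check on the parser);
    each inner list becomes one TD block, as emitted per geometry step
    during an excited-state optimization.
    """
    lines: list[str] = []
    for block in blocks:
        lines.append(" Excitation energies and oscillator strengths:")
        for rec in block:
            lines.append(
                f" Excited State   {rec.state}:      Singlet-A      "
                f"{rec.energy_ev:.4f} eV  {rec.wavelength_nm:.2f} nm  "
                f"f={rec.osc_strength:.4f}  <S**2>=0.000"
            )
        lines.append("")
    return "\n".join(lines)


def parse_td_dft_output(log_text: str) -> list[ExcitationRecord]:
    """Parse excited-state announcement lines from a TD-DFT log.

    Returns one record per announced state in file order.  When geometry
    optimization repeats the TD block, only the final block is returned.
    Wavelengths are recomputed from the energies (hc = 1239.84193 eV nm)
    rather than trusting the printed rounding.  A malformed numeric field
    raises :class:`TDLogParseError` naming the line.
    """
    blocks: list[list[ExcitationRecord]] = []
    current: list[ExcitationRecord] = []
    last_state = 0
    for lineno, line in enumerate(log_text.splitlines(), start=1):
        m = _STATE_RE.search(line)
        if not m:
            if "Excited State" in line and "eV" in line:
                raise TDLogParseError(f"malformed excited-state line {lineno}: {line!r}")
            continue
        try:
            state = int(m.group(1))
            energy = float(m.group(2))
            _wavelength_printed = float(m.group(3))
            osc = float(m.group(4))
        except ValueError as exc:
            raise TDLogParseError(
                f"malformed numeric field on line {lineno}: {line!r}") from exc
        if state <= last_state and current:
            blocks.append(current)
            current = []
        current.append(ExcitationRecord(
            state=state, energy_ev=energy,
            wavelength_nm=HC_EV_NM / energy, osc_strength=osc))
        last_state = state
    if current:
        blocks.append(current)
    return blocks[-1] if blocks else []


def profile_from_runs(s0_records: list[ExcitationRecord],
                      s1_records: list[ExcitationRecord]) -> PhotophysicalProfile:
    """Combine S0-minimum and S1-minimum TD runs into a profile.

    Absorption comes from state 1 of the ground-state-geometry run,
    fluorescence from state 1 of the S1-optimized run.  A missing state 1
    in either run yields an ``evaluation_failed`` profile.
    """
    s0_first = next((r for r in s0_records if r.state == 1), None)
    s1_first = next((r for r in s1_records if r.state == 1), None)
    if s0_first is None or s1_first is None:
        return PhotophysicalProfile.failed()
    return PhotophysicalProfile(
        a_w=HC_EV_NM / s0_first.energy_ev,
        a_i=s0_first.osc_strength,
        f_w=HC_EV_NM / s1_first.energy_ev,
        f_i=s1_first.osc_strength,
    )
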