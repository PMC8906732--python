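"""fluoromcts: de novo fluorescent-molecule generation.

A SMILES language-model prior guides a virtual-loss-parallelized Monte
Carlo tree search that maximizes a four-component photophysical reward
(absorption/fluorescence wavelengths and oscillator strengths), with a
pluggable property oracle and post-run screening statistics.
"""

from importlib import resources

from .analysis import (
    FilterCriteria,
    FilterSummary,
    RunSummary,
    correlation_table,
    filter_candidates,
    passes_filter,
    pearson_correlation,
    percentage,
    summarize_run,
)
from .mcts import (
    CandidateRecord,
    SearchConfig,
    SearchNode,
    backpropagate,
    expand,
    read_ledger,
    rollout,
    search,
    select_leaf,
    selection_score,
    write_ledger,
)
from .molecule_io import (
    Molecule,
    count_aromatic_rings,
    count_conjugate_length,
    load_corpus,
    parse_smiles,
)
from .oracle import (
    CachedEvaluator,
    ExcitationRecord,
    QCJobSpec,
    embed_coordinates,
    evaluate,
    parse_td_dft_output,
    profile_from_runs,
    render_td_dft_log,
    surrogate_evaluate,
    write_td_dft_input,
)
from .prior import (
    Completion,
    NGramPrior,
    PriorModel,
    RecurrentPrior,
    TokenVocabulary,
    UniformPrior,
    detokenize,
    tokenize,
    train_prior,
)
from .reward import (
    PhotophysicalProfile,
    RewardParams,
    os_reward,
    total_reward,
    wavelength_reward,
)

__version__ = "0.1.0"


def toy_corpus_path() -> str:
    """Path to the bundled toy SMILES corpus."""
    return str(resources.files("fluoromcts").joinpath("data/toy_corpus.smi"))
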