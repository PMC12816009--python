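"""Multi-scorer consensus, soft-agreement reliability and ACS.

Five simulated human scorers annotate the same recording, with extra
confusion near stage transitions. The soft-agreement of a scorer is the
average weight the other scorers' (normalized) vote profile puts on
that scorer's own labels; the consensus hypnogram is the per-epoch
majority with ties resolved by the most reliable scorer; ACS compares
two probability-over-stages sequences by mean cosine similarity.
"""

from sleepeval import (
    MultiScorerRecord,
    ScorerNoiseModel,
    acs,
    consensus_hypnogram,
    default_dynamics,
    rank_scorers,
    simulate_hypnogram,
    simulate_scorers,
    soft_agreement,
    soft_consensus,
    stage_metrics,
    to_onehot,
    uniform_error_confusion,
)

truth = simulate_hypnogram(default_dynamics(n_epochs=720), seed=10)
scorers = simulate_scorers(
    truth,
    ScorerNoiseModel(
        base_confusion=uniform_error_confusion(0.93),
        transition_confusion=uniform_error_confusion(0.55),
        transition_window=1,
    ),
    n_scorers=5,
    seed=11,
)
record = MultiScorerRecord("night01", tuple(scorers))

print("per-scorer soft-agreement (1 = always with the majority):")
for sid in record.scorer_ids:
    print(f"  {sid}: {soft_agreement(record, sid):.3f}")

reliability = rank_scorers([record])
print("reliability ranking:", " > ".join(reliability.ranking))
print("scorer set used to evaluate automatic models:", reliability.selected)

consensus = consensus_hypnogram(record)
rep = stage_metrics(consensus, truth)
print(f"consensus vs truth: accuracy {rep.accuracy:.3f} (each scorer alone "
      "is noisier than their majority)")

similarity = acs(soft_consensus(record), to_onehot(truth))
print(f"ACS between the scorers' soft-consensus and the true one-hot "
      f"hypnodensity: {similarity:.3f} (1 = identical profiles)")
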