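"""Train the multi-task graph network and aggregate per participant.

Uses the reference protocol: a 16-sample cohort (12 train / 4 held-out
participants), 2-hop subgraphs with expression + histology node
features, and three heads (methylation subclass, MGMT, CDKN2A/B).
Takes a couple of minutes on one CPU.
"""

from spotgin import experiments as ex

result = ex.multitask(seed=1)

for task in ("methylation_subclass", "mgmt_status", "cdkn2ab_status"):
    rep = result[task]
    print(f"{task:22s} accuracy={rep.accuracy:.3f} "
          f"macro-F1={rep.f1:.3f} (n={rep.n} subgraphs)")

print("\nparticipant-level majority votes:")
votes = result["participant_votes"]
print(votes[["predicted", "vote_fraction", "n_subgraphs"]])
print(f"participant accuracy: {result['participant_accuracy']:.2f}")

# Held-out subgraph accuracies land near 1.0 for subclass and MGMT and
# >=0.9 for the three-class CDKN2A/B head; every held-out participant is
# voted into the right subclass with a large vote fraction.
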