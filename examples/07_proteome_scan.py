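"""Filtered proteome scan: plant known binders, recover them in the top-k.

Candidate (domain, site) pairs must pass three filters — tyrosine residue,
experimentally verified phosphosite, shared subcellular localization —
before the domain model scores and ranks them.
"""

from sh2pep import SVMConfig, ScanConfig, encode_many, make_rule, sample_problem, scan, train
from sh2pep.synth import embed_in_proteome

rule = make_rule(77, n_pairwise=1, additive_scale=0.5)
prob = sample_problem(rule, 400, 400, 0, seed=78)
model = train(encode_many(prob.positives), encode_many(prob.negatives), SVMConfig(2, 1.0))

# three clear binders planted among 60 non-binding decoy sites
candidates = sample_problem(rule, 40, 0, 0, seed=90).positives
planted = [p for p in candidates if rule.score(p) - rule.threshold > 1.5][:3]
decoys = sample_problem(rule, 0, 60, 0, seed=91).negatives
proteome, sites = embed_in_proteome(list(planted) + decoys, seed=92)

localization = {pid: {"cytoplasm"} for pid in proteome}
localization["ABL1"] = {"cytoplasm"}
config = ScanConfig(
    models={"ABL1_SH2": model},
    phosphosites=set(sites),
    localization=localization,
    domain_proteins={"ABL1_SH2": "ABL1"},
    top_k=10,
)
result = scan(proteome, config)

planted_ids = {pid for pid, _ in sites[: len(planted)]}
print(f"scored {result.n_scored} eligible (domain, phosphosite) pairs")
print("top predictions (rank, protein, site, window, score):")
for p in result.predictions["ABL1_SH2"][:5]:
    marker = "  <- planted binder" if p.protein_id in planted_ids else ""
    print(f"  {p.rank:>2}  {p.protein_id}  Y{p.site}  {p.window}  {p.decision_value:+.3f}{marker}")
recovered = planted_ids & {p.protein_id for p in result.predictions["ABL1_SH2"]}
print(f"recovered {len(recovered)}/{len(planted)} planted binders in the top {config.top_k}")
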