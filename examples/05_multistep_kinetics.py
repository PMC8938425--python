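"""Six-state register-shift kinetics: tuning and two-state reduction.

Builds the GS -> I1..I4 -> ES chain (intermediates 1.27 kcal/mol above
the 1.63 kcal/mol excited state), tunes all five transition states
uniformly until the apparent two-state activation free energy matches
the experimental 14.74 kcal/mol, and cross-validates the reduction with
stochastic first-passage sampling.
"""

from rnaexcite import (
    apparent_two_state,
    build_rate_matrix,
    gillespie_first_passage,
    simultaneous_barrier,
    t1_sixstate_chain,
    tune_barriers,
)

chain = tune_barriers(t1_sixstate_chain(), target_dG_act=14.74)
rm = build_rate_matrix(chain)
app = apparent_two_state(rm)
fp = gillespie_first_passage(rm, "GS", "ES", n_paths=10000, seed=1)

largest = max(b - e for b, e in zip(chain.barriers, chain.energies[:-1]))
print(f"tuned transition-state height : {chain.barrier_energies[0]:.2f} kcal/mol")
print(f"apparent activation energy    : {app.dG_act_app:.2f} kcal/mol")
print(f"largest single-step barrier   : {largest:.2f} kcal/mol")
print(f"concerted (all-at-once) barrier: {simultaneous_barrier(chain):.2f} kcal/mol")
print(f"apparent kex / pES            : {app.kex_app:.0f} s^-1 / {100*app.pES_app:.2f} %")
print(f"committor-corrected k1        : {app.k1_committor:.2f} s^-1")
print(f"Gillespie 1/MFPT (10k paths)  : {1/fp.mfpt:.2f} s^-1")
print()
print("Breaking the transition into single-base-pair steps keeps the")
print("apparent barrier only slightly above one step's cost; forcing all")
print("pairs to break at once would accumulate an insurmountable barrier.")
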