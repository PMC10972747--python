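"""Refit SBS signature exposures to clonal versus subclonal mutations of a
simulated patient (clonal mutations drawn tobacco-heavy, subclonal ones
clock-like), mirroring how treatment-era processes are read off clones."""

from ccfevo import (
    SimConfig,
    backward_select,
    build_catalogue,
    eligibility,
    radiation_ratios,
    simulate_patient,
    synthetic_catalog,
)

sim = SimConfig(
    indel_rate=0.05,
    clonal_bounds=(400, 500),
    subclonal_bounds=(150, 200),
    clonal_signature_mix={"SBS4": 0.6, "SBS5": 0.4},      # smoking + clock
    subclonal_signature_mix={"SBS5": 0.7, "SBS31": 0.3},  # clock + platinum scar
)
gt = simulate_patient(3, 2, "C", seed=5, sim=sim)
catalog = synthetic_catalog()  # synthetic stand-in profiles, COSMIC layout

for subset in ("clonal", "subclonal"):
    if subset == "clonal":
        muts = gt.mutations[gt.mutations["clone"] == "C0"]
    else:
        muts = gt.mutations[gt.mutations["clone"] != "C0"]
    counts, skipped = build_catalogue(muts, subset)
    if not eligibility(int(counts.sum()), subset):
        print(f"{subset}: only {counts.sum()} mutations, below the fitting threshold")
        continue
    fit = backward_select(counts, catalog, cost_threshold=0.02, subset=subset)
    active = fit.relative[fit.relative > 0.02].round(3)
    print(f"{subset} ({int(counts.sum())} mutations): {active.to_dict()}")

indel_sub, del_ins = radiation_ratios(gt.mutations)
print(f"indel/substitution burden: {indel_sub}")
# The clonal fit should recover the SBS4/SBS5 mixture and the subclonal
# fit the SBS5/SBS31 mixture; backward selection prunes the remaining
# catalogue signatures whose removal barely changes the fit cost.
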