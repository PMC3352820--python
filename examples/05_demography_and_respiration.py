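"""Serial-transfer demography and community respiration.

Generations per transfer follow from the pre-transfer density series and
the dilution factor; the effective population size uses the bottleneck
census times generations-per-cycle approximation for batch cultures.
Respiration converts cresol-red indicator readings to micrograms of CO2
per ml of medium per hour and contrasts communities reassembled from
monoculture- vs polyculture-evolved isolates.
"""

from ecoevo import TransferLog, community_rates, compare_assemblies, effective_size
from ecoevo.respiration import RespirationSettings
from ecoevo.synthetic import (
    evolved_configs,
    make_default_community,
    simulate_respiration_plate,
    simulate_serial_transfer,
)

community = make_default_community(n_species=4, n_compounds=10, seed=11)

log = simulate_serial_transfer(community, n_transfers=15, dilution=20.0,
                               seed=11, culture_id="mono-A-1")
stats = effective_size(TransferLog.from_frame(log))
print(f"culture {stats.culture_id}: {stats.total_generations:.1f} generations "
      f"over 15 transfers, Ne = {stats.ne:.2e} cells "
      f"({stats.ne_method})")

configs = evolved_configs(community, effect_size=1.0, seed=11)
plate = simulate_respiration_plate(configs, seed=11)
rates = community_rates(plate, RespirationSettings())
by = rates.groupby("history")["rate_ug_per_ml_per_h"]
print("\nmean CO2 release (ug/ml/h) over the 6-h assay:")
print(by.mean().round(2).to_string())

res = compare_assemblies(by.get_group("polyculture").to_numpy(),
                         by.get_group("monoculture").to_numpy(),
                         B=9999, seed=4)
print(f"\npolyculture - monoculture difference: {res.difference:+.2f} ug/ml/h, "
      f"permutation p = {res.p:.4f}")

# Communities built from co-evolved isolates respire more because their
# complementary resource use (plus cross-feeding of by-products) processes
# more of the medium — evolution of niche complementarity raises ecosystem
# productivity.
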