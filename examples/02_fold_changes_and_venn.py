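"""Call regulated miRNAs by fold change and partition two comparisons.

Plants known log2 fold changes in the knockout-vehicle group, calls
regulation at FC > 1.5 (up) / FC < 0.6 (down), and intersects two
comparisons' regulated sets into the eight disjoint Venn cells.
"""

from mirct.differential import group_fold_change, regulated_sets
from mirct.normalization import global_mean_normalize
from mirct.qc import filter_detected
from mirct.set_partition import overlap_summary, venn_partition
from mirct.simulate import PlantedEffect, SimulationConfig, generate_ct_dataset

effects = (
    PlantedEffect("mmu-miR-sim-0001", "P2rx7-KO:vehicle", 2.0),   # true FC = 4
    PlantedEffect("mmu-miR-sim-0002", "P2rx7-KO:vehicle", -1.58),  # true FC = 0.33
    PlantedEffect("mmu-miR-sim-0003", "P2rx7-KO:KA", 2.5),
)
ct, sheet, truth = generate_ct_dataset(SimulationConfig(seed=7, planted_effects=effects))
detected = filter_detected(ct).detected_features
norm = global_mean_normalize(ct, sorted(detected))

sets = {}
for name, test, ref in [
    ("KO-veh vs wt-veh", "P2rx7-KO:vehicle", "wt:vehicle"),
    ("KO-SE vs wt-veh", "P2rx7-KO:KA", "wt:vehicle"),
]:
    records = group_fold_change(norm, sheet, test, ref)
    up, down = regulated_sets(records)
    sets[name] = (up, down)
    planted_here = [r for r in records if r.feature_id in
                    {e.feature_id for e in effects}]
    print(f"{name}: {len(up)} up (FC > 1.5), {len(down)} down (FC < 0.6)")
    for r in sorted(planted_here, key=lambda r: r.feature_id):
        true_fc = 2.0 ** truth.true_log2fc(r.feature_id, test, ref)
        print(f"  {r.feature_id}: measured FC {r.fc:.2f} "
              f"(true {true_fc:.2f}) -> {r.regulation}")

(a_up, a_down), (b_up, b_down) = sets.values()
part = venn_partition(a_up, a_down, b_up, b_down, labels=tuple(sets))
print("\nVenn cells (counts):")
for cell, count in overlap_summary(part).items():
    print(f"  {cell}: {count}")
# features regulated in both comparisons land in the common cells;
# discordant cells hold features up in one comparison and down in the other
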