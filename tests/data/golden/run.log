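events read: 536
events dropped as malformed: 0
profiles read: 6
sessions built: 268
sessionization warnings: 2
nights evaluated: 29
participants without profile (excluded from tables): 0
comparison skipped: mean_total_hours by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_hours_A by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_hours_B by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_hours_C by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_hours_D by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_hours_E by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: mean_gap_hours by use_type: grouping 'use_type' has fewer than two usable levels with data
comparison skipped: prop_adequate by use_type: grouping 'use_type' has fewer than two usable levels with data
association rows: 30
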