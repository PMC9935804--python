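# Data dictionary: the 314-feature catalog

One row per feature, in frozen catalog order. Groups: 35 morphology,
117 morphokinetics, 162 PN dynamics. Aliases f1-f6 mark the final
selected non-redundant subset.

| # | feature | group | alias | description |
|---|---------|-------|-------|-------------|
| 0 | `symmetry_2c` | morphology |  | blastomere size symmetry grade (1 = even .. 4 = very uneven) |
| 1 | `symmetry_4c` | morphology |  | blastomere size symmetry grade (1 = even .. 4 = very uneven) |
| 2 | `fragmentation_2c` | morphology |  | fragmentation percentage of embryo volume |
| 3 | `fragmentation_4c` | morphology |  | fragmentation percentage of embryo volume |
| 4 | `pn_radius_small` | morphology |  | pronucleus radius, pixels |
| 5 | `pn_radius_large` | morphology |  | pronucleus radius, pixels |
| 6 | `pn_area_small` | morphology |  | pronucleus disc area, square pixels |
| 7 | `pn_area_large` | morphology |  | pronucleus disc area, square pixels |
| 8 | `pn_radius_ratio` | morphology |  | pronucleus radius, pixels |
| 9 | `pn_area_ratio` | morphology |  | pronucleus disc area, square pixels |
| 10 | `pn_radius_diff` | morphology |  | pronucleus radius, pixels |
| 11 | `pn_offset_small` | morphology |  | PN-center distance from the ooplasm center, pixels |
| 12 | `pn_offset_large` | morphology |  | PN-center distance from the ooplasm center, pixels |
| 13 | `pn_separation` | morphology |  | distance between the two PN centers, pixels |
| 14 | `npb_count_small` | morphology |  | number of nucleolus precursor bodies |
| 15 | `npb_count_large` | morphology |  | number of nucleolus precursor bodies |
| 16 | `npb_count_total` | morphology |  | number of nucleolus precursor bodies |
| 17 | `npb_count_diff` | morphology |  | number of nucleolus precursor bodies |
| 18 | `npb_maxdist_norm_small` | morphology | f1 | maximum pairwise NPB distance / PN radius (f1 for the small PN) |
| 19 | `npb_maxdist_small` | morphology |  | maximum pairwise NPB distance within one PN, pixels |
| 20 | `npb_maxdist_large` | morphology |  | maximum pairwise NPB distance within one PN, pixels |
| 21 | `npb_maxdist_norm_large` | morphology |  | maximum pairwise NPB distance / PN radius (f1 for the small PN) |
| 22 | `npb_meandist_small` | morphology |  | mean pairwise NPB distance within one PN, pixels |
| 23 | `npb_meandist_large` | morphology |  | mean pairwise NPB distance within one PN, pixels |
| 24 | `npb_spread_small` | morphology |  | RMS NPB distance from the NPB centroid, pixels |
| 25 | `npb_spread_large` | morphology |  | RMS NPB distance from the NPB centroid, pixels |
| 26 | `npb_cross_mindist` | morphology |  | NPB-to-NPB distance between the two PNs, pixels |
| 27 | `npb_cross_meandist` | morphology |  | NPB-to-NPB distance between the two PNs, pixels |
| 28 | `npb_cross_maxdist` | morphology |  | NPB-to-NPB distance between the two PNs, pixels |
| 29 | `cleavage_plane_angle` | morphology |  | first-cleavage-plane orientation angle, degrees (annotated) |
| 30 | `ooplasm_radius` | morphology | f2 | ooplasm radius, pixels (f2) |
| 31 | `zona_inner_radius` | morphology |  | zona pellucida radius / thickness, pixels |
| 32 | `zona_outer_radius` | morphology |  | zona pellucida radius / thickness, pixels |
| 33 | `zona_thickness` | morphology |  | zona pellucida radius / thickness, pixels |
| 34 | `perivitelline_gap` | morphology |  | zona inner radius minus ooplasm radius, pixels |
| 35 | `tPNa` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 36 | `tPNf` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 37 | `t2` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 38 | `t3` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 39 | `t4` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 40 | `t5` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 41 | `t6` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 42 | `t7` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 43 | `t8` | morphokinetics |  | morphokinetic event time, hours post-ICSI |
| 44 | `ivl_tPNa_tPNf` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 45 | `ivl_tPNa_t2` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 46 | `ivl_tPNa_t3` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 47 | `ivl_tPNa_t4` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 48 | `ivl_tPNa_t5` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 49 | `ivl_tPNa_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 50 | `ivl_tPNa_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 51 | `ivl_tPNa_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 52 | `ivl_tPNf_t2` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 53 | `ivl_tPNf_t3` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 54 | `ivl_tPNf_t4` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 55 | `ivl_tPNf_t5` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 56 | `ivl_tPNf_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 57 | `ivl_tPNf_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 58 | `ivl_tPNf_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 59 | `ivl_t2_t3` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 60 | `ivl_t2_t4` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 61 | `ivl_t2_t5` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 62 | `ivl_t2_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 63 | `ivl_t2_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 64 | `ivl_t2_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 65 | `ivl_t3_t4` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 66 | `ivl_t3_t5` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 67 | `ivl_t3_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 68 | `ivl_t3_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 69 | `ivl_t3_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 70 | `ivl_t4_t5` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 71 | `ivl_t4_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 72 | `ivl_t4_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 73 | `ivl_t4_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 74 | `ivl_t5_t6` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 75 | `ivl_t5_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 76 | `ivl_t5_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 77 | `ivl_t6_t7` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 78 | `ivl_t6_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 79 | `ivl_t7_t8` | morphokinetics |  | event-time interval t_later - t_earlier, hours |
| 80 | `ratio_tPNa_tPNf` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 81 | `ratio_tPNa_t2` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 82 | `ratio_tPNa_t3` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 83 | `ratio_tPNa_t4` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 84 | `ratio_tPNa_t5` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 85 | `ratio_tPNa_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 86 | `ratio_tPNa_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 87 | `ratio_tPNa_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 88 | `ratio_tPNf_t2` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 89 | `ratio_tPNf_t3` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 90 | `ratio_tPNf_t4` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 91 | `ratio_tPNf_t5` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 92 | `ratio_tPNf_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 93 | `ratio_tPNf_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 94 | `ratio_tPNf_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 95 | `ratio_t2_t3` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 96 | `ratio_t2_t4` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 97 | `ratio_t2_t5` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 98 | `ratio_t2_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 99 | `ratio_t2_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 100 | `ratio_t2_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 101 | `ratio_t3_t4` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 102 | `ratio_t3_t5` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 103 | `ratio_t3_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 104 | `ratio_t3_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 105 | `ratio_t3_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 106 | `ratio_t4_t5` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 107 | `ratio_t4_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 108 | `ratio_t4_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 109 | `ratio_t4_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 110 | `ratio_t5_t6` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 111 | `ratio_t5_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 112 | `ratio_t5_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 113 | `ratio_t6_t7` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 114 | `ratio_t6_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 115 | `ratio_t7_t8` | morphokinetics |  | event-time ratio t_later / t_earlier |
| 116 | `dlr_tPNa_tPNf` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 117 | `dlr_tPNa_t2` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 118 | `dlr_tPNa_t3` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 119 | `dlr_tPNa_t4` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 120 | `dlr_tPNa_t5` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 121 | `dlr_tPNa_t6` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 122 | `dlr_tPNa_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 123 | `dlr_tPNa_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 124 | `dlr_tPNf_t2` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 125 | `dlr_tPNf_t3` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 126 | `dlr_tPNf_t4` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 127 | `dlr_tPNf_t5` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 128 | `dlr_tPNf_t6` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 129 | `dlr_tPNf_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 130 | `dlr_tPNf_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 131 | `dlr_t2_t3` | morphokinetics | f3 | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 132 | `dlr_t2_t4` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 133 | `dlr_t2_t5` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 134 | `dlr_t2_t6` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 135 | `dlr_t2_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 136 | `dlr_t2_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 137 | `dlr_t3_t4` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 138 | `dlr_t3_t5` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 139 | `dlr_t3_t6` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 140 | `dlr_t3_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 141 | `dlr_t3_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 142 | `dlr_t4_t5` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 143 | `dlr_t4_t6` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 144 | `dlr_t4_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 145 | `dlr_t4_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 146 | `dlr_t5_t6` | morphokinetics | f4 | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 147 | `dlr_t5_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 148 | `dlr_t5_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 149 | `dlr_t6_t7` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 150 | `dlr_t6_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 151 | `dlr_t7_t8` | morphokinetics |  | unsigned distance from the live-birth regression line in the event-pair plane, hours |
| 152 | `pn_step_min_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 153 | `pn_step_max_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 154 | `pn_step_mean_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 155 | `pn_step_median_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 156 | `pn_step_std_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 157 | `pn_step_first_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 158 | `pn_step_last_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 159 | `pn_step_total_small_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 160 | `pn_step_min_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 161 | `pn_step_max_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 162 | `pn_step_mean_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 163 | `pn_step_median_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 164 | `pn_step_std_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 165 | `pn_step_first_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 166 | `pn_step_last_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 167 | `pn_step_total_small_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 168 | `pn_step_min_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 169 | `pn_step_max_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 170 | `pn_step_mean_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 171 | `pn_step_median_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 172 | `pn_step_std_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 173 | `pn_step_first_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 174 | `pn_step_last_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 175 | `pn_step_total_large_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 176 | `pn_step_min_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 177 | `pn_step_max_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 178 | `pn_step_mean_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 179 | `pn_step_median_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 180 | `pn_step_std_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 181 | `pn_step_first_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 182 | `pn_step_last_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 183 | `pn_step_total_large_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 184 | `pn_velocity_min_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 185 | `pn_velocity_max_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 186 | `pn_velocity_mean_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 187 | `pn_velocity_median_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 188 | `pn_velocity_std_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 189 | `pn_velocity_first_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 190 | `pn_velocity_last_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 191 | `pn_velocity_total_small_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 192 | `pn_velocity_min_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 193 | `pn_velocity_max_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 194 | `pn_velocity_mean_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 195 | `pn_velocity_median_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 196 | `pn_velocity_std_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 197 | `pn_velocity_first_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 198 | `pn_velocity_last_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 199 | `pn_velocity_total_small_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 200 | `pn_velocity_min_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 201 | `pn_velocity_max_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 202 | `pn_velocity_mean_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 203 | `pn_velocity_median_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 204 | `pn_velocity_std_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 205 | `pn_velocity_first_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 206 | `pn_velocity_last_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 207 | `pn_velocity_total_large_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 208 | `pn_velocity_min_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 209 | `pn_velocity_max_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 210 | `pn_velocity_mean_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 211 | `pn_velocity_median_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 212 | `pn_velocity_std_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 213 | `pn_velocity_first_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 214 | `pn_velocity_last_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 215 | `pn_velocity_total_large_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 216 | `pn_step_max_ratio_fwd` | pn_dynamics | f5 | per-frame PN displacement statistics, pixels |
| 217 | `pn_step_min_absdiff_fwd` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 218 | `pn_step_max_ratio_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 219 | `pn_step_min_absdiff_rev` | pn_dynamics |  | per-frame PN displacement statistics, pixels |
| 220 | `pn_velocity_max_ratio_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 221 | `pn_velocity_min_absdiff_fwd` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 222 | `pn_velocity_max_ratio_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 223 | `pn_velocity_min_absdiff_rev` | pn_dynamics |  | per-frame PN speed statistics, pixels/hour |
| 224 | `pn_sep_min_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 225 | `pn_sep_max_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 226 | `pn_sep_mean_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 227 | `pn_sep_median_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 228 | `pn_sep_std_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 229 | `pn_sep_first_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 230 | `pn_sep_last_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 231 | `pn_sep_range_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 232 | `pn_sep_iqr_fwd` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 233 | `pn_sep_min_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 234 | `pn_sep_max_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 235 | `pn_sep_mean_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 236 | `pn_sep_median_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 237 | `pn_sep_std_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 238 | `pn_sep_first_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 239 | `pn_sep_last_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 240 | `pn_sep_range_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 241 | `pn_sep_iqr_rev` | pn_dynamics |  | inter-PN distance statistics, pixels |
| 242 | `pn_centerdist_min_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 243 | `pn_centerdist_max_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 244 | `pn_centerdist_mean_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 245 | `pn_centerdist_median_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 246 | `pn_centerdist_std_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 247 | `pn_centerdist_first_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 248 | `pn_centerdist_last_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 249 | `pn_centerdist_range_small_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 250 | `pn_centerdist_min_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 251 | `pn_centerdist_max_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 252 | `pn_centerdist_mean_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 253 | `pn_centerdist_median_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 254 | `pn_centerdist_std_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 255 | `pn_centerdist_first_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 256 | `pn_centerdist_last_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 257 | `pn_centerdist_range_small_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 258 | `pn_centerdist_min_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 259 | `pn_centerdist_max_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 260 | `pn_centerdist_mean_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 261 | `pn_centerdist_median_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 262 | `pn_centerdist_std_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 263 | `pn_centerdist_first_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 264 | `pn_centerdist_last_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 265 | `pn_centerdist_range_large_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 266 | `pn_centerdist_min_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 267 | `pn_centerdist_max_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 268 | `pn_centerdist_mean_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 269 | `pn_centerdist_median_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 270 | `pn_centerdist_std_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 271 | `pn_centerdist_first_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 272 | `pn_centerdist_last_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 273 | `pn_centerdist_range_large_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 274 | `pn_centerdist_min_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 275 | `pn_centerdist_max_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 276 | `pn_centerdist_mean_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 277 | `pn_centerdist_median_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 278 | `pn_centerdist_std_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 279 | `pn_centerdist_first_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 280 | `pn_centerdist_last_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 281 | `pn_centerdist_range_small_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 282 | `pn_centerdist_min_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 283 | `pn_centerdist_max_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 284 | `pn_centerdist_mean_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 285 | `pn_centerdist_median_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 286 | `pn_centerdist_std_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 287 | `pn_centerdist_first_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 288 | `pn_centerdist_last_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 289 | `pn_centerdist_range_small_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 290 | `pn_centerdist_min_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 291 | `pn_centerdist_max_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 292 | `pn_centerdist_mean_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 293 | `pn_centerdist_median_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 294 | `pn_centerdist_std_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 295 | `pn_centerdist_first_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 296 | `pn_centerdist_last_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 297 | `pn_centerdist_range_large_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 298 | `pn_centerdist_min_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 299 | `pn_centerdist_max_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 300 | `pn_centerdist_mean_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 301 | `pn_centerdist_median_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 302 | `pn_centerdist_std_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 303 | `pn_centerdist_first_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 304 | `pn_centerdist_last_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 305 | `pn_centerdist_range_large_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 306 | `pn_centerdist_absdiff_tpnf_fwd_raw` | pn_dynamics | f6 | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 307 | `pn_centerdist_absdiff_mean_fwd_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 308 | `pn_centerdist_absdiff_tpnf_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 309 | `pn_centerdist_absdiff_mean_rev_raw` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 310 | `pn_centerdist_absdiff_tpnf_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 311 | `pn_centerdist_absdiff_mean_fwd_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 312 | `pn_centerdist_absdiff_tpnf_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
| 313 | `pn_centerdist_absdiff_mean_rev_norm` | pn_dynamics |  | PN distance from embryo (ooplasm) center, pixels; 'norm' = / ooplasm radius |
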