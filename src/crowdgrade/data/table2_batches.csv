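batch,scale,mean_time_s,ci_low_s,ci_high_s,pay_per_rating,commission_rate,raters_per_image,published_wage,published_cost
two_category,two_cat,25.16,21.93,28.38,0.10,0.10,10,14.31,1.10
three_category,three_cat,50.87,43.18,58.55,0.10,0.10,10,7.08,1.10
four_category,four_cat,54.52,46.15,62.88,0.10,0.10,10,6.60,1.10
four_category_improved_training,four_cat,50.98,39.66,62.30,0.10,0.10,10,7.06,1.10
four_category_increased_approval,four_cat,38.79,31.65,45.93,0.10,0.10,10,9.28,1.10
four_category_master_graders,four_cat,44.14,36.00,52.27,0.15,0.30,10,12.23,1.95
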