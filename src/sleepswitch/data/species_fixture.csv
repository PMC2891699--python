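# Editable species-metrics table (17 species across 7 orders).
# ALL metric values below are PLACEHOLDERS (placeholder=1): transcribe daily
# sleep and bout-length ranges from the primary literature before use.
# Rows with placeholder=1 are skipped by sleepswitch.mapping.load_species_table.
species,daily_sleep_lo_h,daily_sleep_hi_h,bout_lo_min,bout_hi_min,body_mass_kg,chi_upper_bound_h,placeholder
rat,12.0,14.0,5.0,8.0,0.3,,1
mouse,12.0,13.0,3.0,6.0,0.02,,1
hamster,13.0,15.0,5.0,10.0,0.1,,1
squirrel,14.0,16.0,8.0,15.0,0.5,,1
chinchilla,12.0,13.0,5.0,10.0,0.5,,1
eastern_mole,8.0,9.0,10.0,20.0,0.075,,1
asian_elephant,3.0,5.0,60.0,120.0,3000.0,,1
dog,9.0,11.0,20.0,50.0,15.0,,1
jaguar,10.0,11.0,40.0,80.0,90.0,,1
cat,12.0,14.0,20.0,60.0,4.0,,1
fox,9.0,11.0,20.0,50.0,5.0,,1
opossum,17.0,19.0,30.0,90.0,2.5,,1
armadillo,17.0,18.0,30.0,90.0,4.0,,1
common_shrew,8.0,10.0,5.0,10.0,0.01,,1
rhesus_monkey,9.0,12.0,300.0,600.0,7.0,72.0,1
slow_loris,10.0,12.0,300.0,600.0,1.2,72.0,1
human,7.0,9.0,400.0,500.0,70.0,72.0,1
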