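vessel_category,volunteer_id,field_strength,score
carotid_siphon,1,7T,3
carotid_siphon,1,3T,4
carotid_siphon,2,7T,3
carotid_siphon,2,3T,3
carotid_siphon,3,7T,3
carotid_siphon,3,3T,3
carotid_siphon,4,7T,3
carotid_siphon,4,3T,3
ophthalmic,1,7T,3
ophthalmic,1,3T,4
ophthalmic,2,7T,4
ophthalmic,2,3T,3
ophthalmic,3,7T,1
ophthalmic,3,3T,1
ophthalmic,4,7T,1
ophthalmic,4,3T,3
lenticulostriate,1,7T,4
lenticulostriate,1,3T,3
lenticulostriate,2,7T,4
lenticulostriate,2,3T,2
lenticulostriate,3,7T,4
lenticulostriate,3,3T,3
lenticulostriate,4,7T,4
lenticulostriate,4,3T,3
anterior_choroidal,1,7T,3
anterior_choroidal,1,3T,3
anterior_choroidal,2,7T,3
anterior_choroidal,2,3T,3
anterior_choroidal,3,7T,3
anterior_choroidal,3,3T,3
anterior_choroidal,4,7T,3
anterior_choroidal,4,3T,2
thalamic_perforating,1,7T,4
thalamic_perforating,1,3T,2
thalamic_perforating,2,7T,3
thalamic_perforating,2,3T,0
thalamic_perforating,3,7T,2
thalamic_perforating,3,3T,0
thalamic_perforating,4,7T,3
thalamic_perforating,4,3T,0
pontine_perforating,1,7T,0
pontine_perforating,1,3T,0
pontine_perforating,2,7T,2
pontine_perforating,2,3T,0
pontine_perforating,3,7T,1
pontine_perforating,3,3T,0
pontine_perforating,4,7T,1
pontine_perforating,4,3T,0
cerebral_arteries,1,7T,4
cerebral_arteries,1,3T,4
cerebral_arteries,2,7T,4
cerebral_arteries,2,3T,4
cerebral_arteries,3,7T,4
cerebral_arteries,3,3T,4
cerebral_arteries,4,7T,4
cerebral_arteries,4,3T,4
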