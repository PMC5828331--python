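coded_label,category,faculty,student,junior_doctor
Ear examination,new_technical,0,2,3
First line ultrasounds utilization,new_technical,1,3,1
Blood pressure measurement,new_technical,1,1,2
Earwax removal,new_technical,0,1,2
Drugs dilution,new_technical,0,1,2
Delivery assistance,new_technical,0,0,3
I.V. kit preparation,new_technical,0,0,2
Anterior nasal packing,new_technical,0,0,2
Correct fill-in of medical prescription paper,new_technical,0,0,2
Medical vitals collection,new_technical,2,0,0
Carotid sinus massage,new_technical,0,1,0
Minor surgery,new_technical,0,1,0
Fundus oculi examination without pupil dilation,new_technical,1,0,0
Tracheal aspiration,new_technical,1,0,0
Pediatric BLS,new_technical,1,0,0
Scrotal transillumination,new_technical,1,0,0
Problems-oriented medical chart writing,new_technical,1,0,0
Bone marrow aspiration,new_technical,1,0,0
Small foreign body remotion from the skin,new_technical,0,0,1
Infusion pump management,new_technical,0,0,1
General practitioner software utilization,new_technical,0,0,1
Elastic bandage compression,new_technical,0,0,1
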