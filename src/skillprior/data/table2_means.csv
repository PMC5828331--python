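item_id,label,printed_desirability,faculty_essentialness_mean,faculty_essentialness_disp,student_autonomy_mean,student_autonomy_disp,junior_doctor_autonomy_mean,junior_doctor_autonomy_disp,faculty_utility_mean,faculty_utility_disp,student_utility_mean,student_utility_disp,junior_doctor_utility_mean,junior_doctor_utility_disp
urinary_catheter,Urinary catheter placement and removal in males and females,0.77,7.6,2.2,2.2,1.7,2.5,2.1,7.8,2.1,7.9,2.0,7.8,2.0
ng_tube,Nasogastric tube insertion and removal,0.75,8.1,1.4,2.3,2.0,2.7,2.1,7.6,1.9,7.4,1.9,7.1,2.5
abscess_drainage,Superficial abscesses incision and drainage,0.70,7.1,1.5,2.3,1.9,2.9,2.4,7.8,1.8,7.4,2.2,7.0,2.6
pleural_tap,Pleural tap,0.69,6.1,2.2,1.6,1.5,1.9,1.9,7.0,2.1,7.1,2.1,6.5,2.8
lumbar_puncture,Lumbar puncture,0.69,5.6,2.7,1.3,1.0,1.3,0.9,7.0,2.4,6.9,2.2,6.2,3.0
cricothyrotomy,Cricothyrotomy,0.68,5.4,2.6,1.3,0.9,1.1,0.5,6.7,2.8,6.8,2.4,6.8,2.8
paracentesis,Paracentesis,0.67,6.6,2.5,2.0,1.9,2.6,2.3,6.7,2.6,7.4,2.0,6.4,2.7
chest_tube,Chest tube insertion and removal,0.65,5.3,2.4,1.7,1.3,1.8,1.7,6.6,2.6,7.3,2.2,6.9,2.5
intubation,Nasal and oral intubation,0.65,6.0,2.7,2.9,2.0,2.4,1.9,7.3,2.5,7.4,2.3,7.2,2.6
simple_suture,Continuous simple suture placement and removal,0.63,8.5,1.0,3.9,2.7,5.1,3.1,8.4,1.5,8.1,2.0,8.4,1.4
burn_medication,First degree burn medication,0.63,8.3,1.0,2.9,2.4,4.8,3.0,7.4,2.1,7.4,2.3,7.0,2.7
ocular_swab,Ocular swab,0.62,6.7,2.3,2.6,2.4,3.1,2.6,6.5,2.5,6.9,2.5,5.9,2.9
polytrauma_immobilization,Polytraumatized patient immobilization for transport,0.61,8.6,0.8,5.1,2.4,4.2,2.6,8.5,1.3,7.9,1.9,7.7,2.3
venturi_mask,Venturi mask assembly and placement,0.61,7.8,2.2,4.2,2.7,3.9,2.9,7.3,2.4,7.4,2.1,7.2,2.4
metal_clips,Superficial metal clips placement and removal,0.59,7.5,1.8,3.5,2.6,4.9,2.9,7.5,2.6,7.2,2.4,7.1,2.4
wound_dressing,Wound dressing placement,0.57,8.6,0.8,4.5,2.4,5.4,2.8,8.0,1.9,7.7,2.3,7.7,2.3
urethral_swab,Urethral swab,0.56,6.5,2.3,3.2,2.6,3.7,2.9,6.2,2.5,6.9,2.4,6.0,2.8
surgical_kit,Minor surgery surgical kit preparation,0.56,7.7,1.3,4.1,2.4,5.1,2.5,7.6,2.0,7.4,2.2,7.0,2.3
vaginal_swab,Vaginal swab,0.55,6.7,2.3,3.6,2.8,4.0,3.0,6.6,2.5,6.9,2.4,6.0,2.8
spirometry,Spirometry,0.55,6.1,2.1,3.1,2.4,3.1,2.5,5.7,2.6,6.3,2.6,5.7,2.9
cervical_collar,Cervical collar placement,0.54,7.8,2.0,5.4,2.5,4.8,2.7,7.8,2.3,7.9,1.8,8.0,1.8
butterfly_catheter,Butterfly catheter placement and removal for venous puncture,0.54,8.9,0.3,5.3,2.6,5.4,2.6,8.1,1.7,7.7,2.4,7.8,2.2
radial_puncture,Radial artery puncture and blood sample,0.54,8.5,0.8,5.1,2.9,5.6,2.5,8.5,1.1,7.8,2.0,7.3,2.3
nasal_swab,Nasal swab,0.53,7.7,1.6,4.1,2.9,4.9,3.0,6.6,2.4,6.9,2.4,6.1,2.8
gynecologic_exam,Gynecologic exam,0.53,5.8,3.0,4.5,2.5,3.1,2.7,6.5,2.8,6.9,2.5,6.4,2.6
wound_cleansing,"Open wounds (cuts, sores, ulcers, and fistulas) cleansing and medication",0.53,8.7,0.5,4.7,2.4,6.0,2.6,7.6,2.2,7.7,2.3,7.4,2.5
bag_valve_mask,Bag valve mask (ambu bag) utilization,0.51,7.7,2.1,5.8,2.7,4.9,3.2,7.8,2.3,7.8,2.1,7.8,2.0
heimlich,Heimlich maneuver,0.50,8.6,1.4,6.0,2.4,5.9,2.3,8.6,1.1,8.3,1.8,8.4,1.6
pharyngeal_swab,Pharingeal swab,0.49,7.6,1.5,5.0,2.8,5.0,3.0,6.8,2.4,7.0,2.4,6.0,2.9
inguinal_exam,Inguinal canal examination,0.49,8.5,1.0,5.7,2.5,5.4,2.9,7.6,1.9,6.8,2.7,7.0,2.6
aed,Automated external defibrillator (AED) placement and utilization,0.48,8.7,0.8,6.1,2.3,6.3,2.5,8.6,1.3,8.4,1.7,8.6,1.3
cpr,Cardiopulmonary resuscitation,0.43,8.7,1.0,6.6,2.0,6.6,2.3,8.7,1.1,8.5,1.5,8.7,1.1
glucometer,Glucometer utilization,0.42,8.7,0.7,5.9,2.7,6.6,2.6,7.4,2.4,6.9,2.8,6.9,2.7
im_injection,Intramuscular injection,0.40,8.9,0.3,6.5,2.4,6.8,2.8,7.9,1.9,7.4,2.6,7.4,2.6
sc_injection,Subcutaneous injection,0.40,8.9,0.3,6.1,2.5,7.0,2.6,7.7,2.0,7.3,2.7,7.3,2.7
urine_collection,Patient's urine collection,0.37,8.4,1.7,6.5,2.5,6.7,2.5,6.8,2.8,7.0,2.7,6.7,2.8
blood_smear,Peripheral blood smear,0.34,6.8,2.5,6.4,2.3,6.4,2.4,6.8,2.6,6.4,2.7,5.5,2.8
ecg,Electrocardiograph placement and utilization,0.29,8.6,1.4,7.5,1.9,7.4,2.2,8.0,1.8,7.1,2.6,7.8,2.3
rectal_exploration,Rectal exploration,0.29,8.5,1.3,7.4,2.1,7.5,2.0,7.9,1.9,6.9,2.9,7.2,2.5
ppe_usage,Personal protective equipment (PPE) usage,0.25,9.0,0.2,7.6,2.0,7.9,1.9,7.7,2.4,7.1,2.9,7.4,2.7
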